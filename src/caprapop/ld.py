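"""Linkage disequilibrium decay and LD-based effective population size.

r-squared is the genotypic (composite) measure: the squared Pearson
correlation of unphased dosage vectors over samples called at both SNPs.
The decay curve is fitted to the Sved/Hill–Weir expectation
E[r2](d) = 1/(1 + 4 N c(d)) + 1/(2n), with c(d) the recombination fraction
from a linear bp-to-Morgan map.  Historical effective population size per
distance bin follows the Corbin-style inversion
Ne(c) = (1/(4c)) (1/r2_adj - alpha), with r2_adj = mean r2 - 1/(2n) and the
generation time t = 1/(2c).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import MISSING, GenotypeDataset

#: default linear genetic map: 1 Mb per cM -> 1e8 bp per Morgan
BP_PER_MORGAN = 100_000_000.0


@dataclasses.dataclass
class LDPairSet:
    pairs: pd.DataFrame          # snp_i, snp_j, chromosome, dist_bp, r2
    n_skipped: int               # pairs dropped (few obs / zero variance)

    @property
    def mean_r2(self) -> float:
        return float(self.pairs["r2"].mean())

    @property
    def mean_dist_bp(self) -> float:
        return float(self.pairs["dist_bp"].mean())


@dataclasses.dataclass
class LDDecayFit:
    N: float                     # fitted effective size
    offset: float                # the fixed 1/(2n) sample-size term
    rss: float
    converged: bool


def pairwise_r2(ds: GenotypeDataset, breed: str | None = None,
                min_dist: int = 1_000, max_dist: int = 1_000_000) -> LDPairSet:
    """All intra-chromosomal SNP pairs with bp distance in [min_dist, max_dist].

    Pairs with fewer than 3 jointly called samples or zero variance at either
    SNP are skipped and counted.
    """
    sub = ds.subset_breed(breed) if breed is not None else ds
    if sub.n_samples < 2:
        raise ValueError("need at least two samples")
    if not sub.markers_sorted():
        raise ValueError("markers must be sorted")
    d = sub.dosage_float()
    chrom = sub.chromosomes
    bp = sub.bp_positions
    ids = np.array(sub.snp_ids)
    rows = []
    skipped = 0
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        pos = bp[sel]
        for ii in range(sel.size):
            x = d[:, sel[ii]]
            # pairs within the distance window to the right
            jj = ii + 1
            hi = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            lo = np.searchsorted(pos, pos[ii] + min_dist, side="left")
            for kk in range(max(jj, lo), hi):
                y = d[:, sel[kk]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3:
                    skipped += 1
                    continue
                xv, yv = x[ok], y[ok]
                sx, sy = xv.std(), yv.std()
                if sx == 0 or sy == 0:
                    skipped += 1
                    continue
                r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
                rows.append((ids[sel[ii]], ids[sel[kk]], c,
                             int(pos[kk] - pos[ii]), r * r))
    pairs = pd.DataFrame(rows, columns=["snp_i", "snp_j", "chromosome",
                                        "dist_bp", "r2"])
    return LDPairSet(pairs=pairs, n_skipped=skipped)


def adjacent_pairs_in_ld(pairset: LDPairSet, r2_cutoff: float = 0.2) -> pd.DataFrame:
    """Per-chromosome count of pairs above an r2 cutoff."""
    p = pairset.pairs
    return (p.assign(in_ld=p["r2"] >= r2_cutoff)
             .groupby("chromosome", as_index=False)["in_ld"].sum())


def fit_ld_decay(pairset: LDPairSet, n_samples: int,
                 bp_per_morgan: float = BP_PER_MORGAN) -> LDDecayFit:
    """Nonlinear least-squares fit of the Sved expectation to observed pairs."""
    p = pairset.pairs
    if len(p) < 50:
        raise ValueError("need at least 50 pairs to fit the decay curve")
    c = p["dist_bp"].to_numpy() / bp_per_morgan
    r2 = p["r2"].to_numpy()
    offset = 1.0 / (2.0 * n_samples)

    def model(cc, N):
        return 1.0 / (1.0 + 4.0 * N * cc) + offset

    try:
        popt, _ = curve_fit(model, c, r2, p0=[100.0],
                            bounds=(1e-6, 1e9), maxfev=10_000)
        N = float(popt[0])
        rss = float(np.sum((r2 - model(c, N)) ** 2))
        converged = True
    except RuntimeError:
        N, rss, converged = np.nan, float(np.sum((r2 - np.mean(r2)) ** 2)), False
    return LDDecayFit(N=N, offset=offset, rss=rss, converged=converged)


def ne_trajectory(pairset: LDPairSet, n_samples: int, n_bins: int = 12,
                  alpha: float = 1.0,
                  bp_per_morgan: float = BP_PER_MORGAN) -> pd.DataFrame:
    """Historical Ne per log-spaced distance bin.

    Each bin's representative recombination fraction c is its mean pair
    distance over the bp->Morgan map; generations t = 1/(2c);
    Ne = (1/(4c)) (1/r2_adj - alpha) with r2_adj = mean r2 - 1/(2 n_samples).
    Bins whose adjusted r2 is at or below the 1/alpha floor are flagged and
    given no Ne.
    """
    p = pairset.pairs
    if p.empty:
        raise ValueError("no LD pairs")
    dmin, dmax = p["dist_bp"].min(), p["dist_bp"].max()
    edges = np.unique(np.geomspace(max(dmin, 1), dmax + 1, n_bins + 1))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (p["dist_bp"] >= lo) & (p["dist_bp"] < hi)
        if sel.sum() == 0:
            continue
        mean_d = p.loc[sel, "dist_bp"].mean()
        c = mean_d / bp_per_morgan
        r2_adj = p.loc[sel, "r2"].mean() - 1.0 / (2.0 * n_samples)
        t = 1.0 / (2.0 * c)
        if r2_adj <= 0 or (1.0 / r2_adj - alpha) <= 0:
            rows.append({"bin_lo_bp": lo, "bin_hi_bp": hi, "c": c, "t": t,
                         "n_pairs": int(sel.sum()), "mean_r2_adj": r2_adj,
                         "Ne": np.nan, "flagged": True})
            continue
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha)
        rows.append({"bin_lo_bp": lo, "bin_hi_bp": hi, "c": c, "t": t,
                     "n_pairs": int(sel.sum()), "mean_r2_adj": r2_adj,
                     "Ne": ne, "flagged": False})
    return pd.DataFrame(rows)
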
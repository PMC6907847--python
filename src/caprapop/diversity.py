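"""Per-breed diversity indices and inbreeding coefficients.

Covers observed/expected heterozygosity with Nei's small-sample correction,
polymorphic-locus counts, per-site nucleotide diversity, the per-individual
method-of-moments inbreeding coefficient F_IS, VanRaden's genomic relationship
matrix and its diagonal-based F_GRM, and the Weir–Cockerham (1984) FST
variance-components estimator (per-SNP and global ratio-of-sums).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset


@dataclasses.dataclass
class DiversitySummary:
    breed: str
    n_samples: int
    n_snps_used: int
    n_polymorphic: int
    pct_polymorphic: float
    mean_ho: float
    sd_ho: float
    mean_he: float
    sd_he: float
    pi: float


@dataclasses.dataclass
class FstResult:
    """Weir–Cockerham variance components per SNP and their global ratio.

    ``theta`` is a/(a+b+c) per SNP (NaN where the SNP is monomorphic across
    all populations); ``theta_global`` is sum(a)/sum(a+b+c) over defined SNPs.
    """
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    theta_global: float

    @property
    def n_negative(self) -> int:
        return int(np.nansum(self.theta < 0))

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.theta).sum())


def per_snp_heterozygosity(ds: GenotypeDataset, breed: str | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Observed and unbiased expected heterozygosity per SNP within a breed.

    He uses Nei's correction 2n/(2n-1) * (1 - p^2 - q^2) with n the called
    diploid count.  SNPs with fewer than two called genotypes are NaN.
    """
    sub = ds.subset_breed(breed) if breed is not None else ds
    d = sub.dosage
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called, d == 1, False).sum(axis=0) / n
        p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
        he = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    bad = n < 2
    ho[bad] = np.nan
    he[bad] = np.nan
    return ho, he


def diversity_summary(ds: GenotypeDataset, breed: str) -> DiversitySummary:
    """Table-1-style per-breed summary (Np, Np%, Ho, He, pi).

    pi is the mean unbiased per-site heterozygosity over the SNPs usable in
    the breed (the mean pairwise difference per SNP site); SNPs with fewer
    than two called genotypes are skipped and excluded from the denominator.
    """
    sub = ds.subset_breed(breed)
    if sub.n_samples < 2:
        raise ValueError(f"breed {breed!r} has <2 samples")
    ho, he = per_snp_heterozygosity(sub)
    used = np.isfinite(he)
    d = sub.dosage
    called = d != MISSING
    p = np.where(called, d, 0).sum(axis=0) / np.maximum(2.0 * called.sum(axis=0), 1)
    poly = used & (p > 0) & (p < 1)
    return DiversitySummary(
        breed=breed, n_samples=sub.n_samples,
        n_snps_used=int(used.sum()),
        n_polymorphic=int(poly.sum()),
        pct_polymorphic=100.0 * poly.sum() / max(ds.n_markers, 1),
        mean_ho=float(np.nanmean(ho[used])), sd_ho=float(np.nanstd(ho[used])),
        mean_he=float(np.nanmean(he[used])), sd_he=float(np.nanstd(he[used])),
        pi=float(np.nanmean(he[used])))


def diversity_table(ds: GenotypeDataset) -> pd.DataFrame:
    rows = [dataclasses.asdict(diversity_summary(ds, b))
            for b in sorted(set(ds.breeds))]
    return pd.DataFrame(rows)


def fis_per_individual(ds: GenotypeDataset, by_breed: bool = True) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (L - E_hom) over the individual's called SNPs, with
    E_hom computed from allele frequencies in the individual's own breed
    cohort (``by_breed=True``, the "individual within subpopulation" reading)
    or the pooled cohort.
    """
    out = np.full(ds.n_samples, np.nan)
    groups = ({b: np.flatnonzero(ds.breeds == b) for b in set(ds.breeds)}
              if by_breed else {"all": np.arange(ds.n_samples)})
    for idx in groups.values():
        sub = ds.subset(sample_idx=idx)
        d = sub.dosage
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
            # per-SNP expected homozygosity with small-sample correction
            exp_hom_snp = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
        usable = (n >= 2) & np.isfinite(exp_hom_snp)
        for row, i in enumerate(idx):
            use = called[row] & usable
            L = int(use.sum())
            if L == 0:
                continue
            o_hom = float((d[row, use] != 1).sum())
            e_hom = float(exp_hom_snp[use].sum())
            denom = L - e_hom
            out[i] = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else np.nan
    return out


def grm_vanraden(ds: GenotypeDataset, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = ZZ' / (2 sum p_j(1-p_j)) with Z = dosage - 2p and missing genotypes
    imputed to the frequency mean (Z = 0).
    """
    d = ds.dosage_float()
    if freqs is None:
        freqs = np.nanmean(d, axis=0) / 2.0
    Z = d - 2.0 * freqs
    Z[np.isnan(Z)] = 0.0
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: zero GRM denominator")
    return (Z @ Z.T) / denom


def fgrm(ds: GenotypeDataset, by_breed: bool = True) -> np.ndarray:
    """Genomic inbreeding from the GRM diagonal, F = diag(G) - 1, computed
    within each breed cohort by default."""
    out = np.full(ds.n_samples, np.nan)
    groups = ({b: np.flatnonzero(ds.breeds == b) for b in set(ds.breeds)}
              if by_breed else {"all": np.arange(ds.n_samples)})
    for idx in groups.values():
        G = grm_vanraden(ds.subset(sample_idx=idx))
        out[idx] = np.diag(G) - 1.0
    return out


def fst_weir_cockerham(ds: GenotypeDataset,
                       pop_labels: np.ndarray | None = None) -> FstResult:
    """Weir & Cockerham (1984) FST for a biallelic locus set.

    Computes the among-population (a), among-individual-within-population (b)
    and within-individual (c) variance components per SNP from population
    sample sizes, allele frequencies and observed heterozygote proportions.
    SNPs monomorphic across all populations, or with fewer than two called
    genotypes in any population, are excluded from per-SNP values and sums.
    """
    labels = np.asarray(pop_labels if pop_labels is not None else ds.breeds)
    pops = sorted(set(labels))
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    m = ds.n_markers
    n_mat = np.zeros((r, m))      # called diploid counts
    p_mat = np.zeros((r, m))      # allele-b frequency
    h_mat = np.zeros((r, m))      # observed het proportion
    for k, pop in enumerate(pops):
        d = ds.dosage[labels == pop]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mat[k] = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
            h_mat[k] = np.where(called, d == 1, False).sum(axis=0) / n
        n_mat[k] = n
    ok = (n_mat >= 2).all(axis=0)
    poly = ~((p_mat <= 0).all(axis=0) | (p_mat >= 1).all(axis=0))
    # monomorphic across all pops means identical fixed freq everywhere
    same_fixed = np.zeros(m, dtype=bool)
    with np.errstate(invalid="ignore"):
        same_fixed = ((p_mat == p_mat[0]).all(axis=0)
                      & ((p_mat[0] == 0) | (p_mat[0] == 1)))
    defined = ok & ~same_fixed & poly

    n_bar = n_mat.mean(axis=0)
    n_tot = n_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_tot - (n_mat**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n_mat * p_mat).sum(axis=0) / n_tot
        s2 = (n_mat * (p_mat - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_mat * h_mat).sum(axis=0) / n_tot
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar)
                                       - (r - 1) / r * s2
                                       - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    for arr in (a, b, c):
        arr[~defined] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    num = np.nansum(a[defined])
    den = np.nansum((a + b + c)[defined])
    theta_global = float(num / den) if den != 0 else np.nan
    return FstResult(a=a, b=b, c=c, theta=theta, theta_global=theta_global)
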
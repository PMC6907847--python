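"""Discriminatory SNP panels and likelihood-based breed assignment.

Panel construction combines three routes: (i) the upper 0.995 percentile of
the per-SNP Weir–Cockerham FST distribution; (ii) the intersection of the
top-200 SNPs under each of three metrics — allele-frequency difference Delta,
per-SNP FST, and Rosenberg's informativeness for assignment In — on the whole
cohort; (iii) the same multi-metric intersection built on a stratified
training split and evaluated on the held-out half.  The consensus panel is
the three-way intersection.

Assignment follows the GeneClass2 conventions: a frequency-based criterion
(Hardy–Weinberg genotype probabilities from breed allele frequencies, zero
frequencies replaced by 0.01) and a Bayesian criterion (Rannala–Mountain
posterior-predictive genotype probabilities under a per-allele Dirichlet(1/k)
prior), both with leave-one-out frequencies for the individual's own breed.
Exclusion tests use Paetkau Monte Carlo resampling of multilocus genotypes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .diversity import fst_weir_cockerham
from .io import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# per-SNP discriminatory statistics
# ---------------------------------------------------------------------------

def breed_allele_freqs(ds: GenotypeDataset) -> dict[str, np.ndarray]:
    """Counted-allele frequency per SNP within each breed."""
    out = {}
    for b in sorted(set(ds.breeds)):
        d = ds.subset_breed(b).dosage
        called = d != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[b] = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * n),
                              np.nan)
    return out


def delta_stat(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Absolute allele-frequency difference between two populations."""
    return np.abs(np.asarray(p1) - np.asarray(p2))


def informativeness_in(freqs: np.ndarray) -> np.ndarray:
    """Rosenberg's informativeness for assignment (nats), biallelic case.

    ``freqs`` is pops x SNPs.  For each allele a:
    -p_bar log p_bar + (1/K) sum_k p_k log p_k, summed over both alleles,
    with 0 log 0 := 0.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    K = freqs.shape[0]

    def xlogx(x):
        with np.errstate(invalid="ignore", divide="ignore"):
            v = x * np.log(x)
        return np.where(x > 0, v, 0.0)

    total = np.zeros(freqs.shape[1])
    for allele_freq in (freqs, 1.0 - freqs):
        p_bar = allele_freq.mean(axis=0)
        total += -xlogx(p_bar) + xlogx(allele_freq).sum(axis=0) / K
    return np.clip(total, 0.0, None)


@dataclasses.dataclass
class PanelScores:
    """Per-SNP discriminatory statistics with per-metric descending ranks."""
    table: pd.DataFrame  # snp_id, theta, delta, In, rank_theta, rank_delta, rank_in


def panel_scores(ds: GenotypeDataset) -> PanelScores:
    freqs = breed_allele_freqs(ds)
    breeds = sorted(freqs)
    if len(breeds) != 2:
        raise ValueError("panel scoring expects exactly two breeds")
    theta = fst_weir_cockerham(ds).theta
    delta = delta_stat(freqs[breeds[0]], freqs[breeds[1]])
    In = informativeness_in(np.vstack([freqs[b] for b in breeds]))
    tab = pd.DataFrame({"snp_id": ds.snp_ids, "theta": theta,
                        "delta": delta, "In": In})
    for col in ("theta", "delta", "In"):
        # descending score, ties broken by snp_id for determinism
        order = tab.sort_values([col, "snp_id"], ascending=[False, True],
                                na_position="last")
        tab.loc[order.index, f"rank_{col}"] = np.arange(1, len(tab) + 1)
    return PanelScores(table=tab)


def fst_percentile_panel(theta: np.ndarray, snp_ids: list[str],
                         q: float = 0.995) -> tuple[set[str], float]:
    """SNPs at or above the q-quantile of the defined per-SNP FST values."""
    theta = np.asarray(theta, dtype=float)
    defined = np.isfinite(theta)
    thr = float(np.quantile(theta[defined], q))
    ids = np.asarray(snp_ids)
    return set(ids[defined & (theta >= thr)]), thr


def tres_panel(ds: GenotypeDataset, top_n: int = 200) -> set[str]:
    """Intersection of the top-N SNP lists under Delta, FST and In."""
    scores = panel_scores(ds).table
    sets = []
    for col in ("delta", "theta", "In"):
        top = scores.loc[scores[f"rank_{col}"] <= top_n, "snp_id"]
        sets.append(set(top))
    return sets[0] & sets[1] & sets[2]


def stratified_split(ds: GenotypeDataset, split_fraction: float = 0.5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-breed random split into training/test index arrays."""
    rng = np.random.default_rng(seed)
    breeds = ds.breeds
    train, test = [], []
    for b in sorted(set(breeds)):
        idx = np.flatnonzero(breeds == b)
        rng.shuffle(idx)
        k = int(round(split_fraction * idx.size))
        if k < 2 or idx.size - k < 2:
            raise ValueError(f"split leaves breed {b!r} with <2 samples on a side")
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.sort(np.array(train)), np.sort(np.array(test))


@dataclasses.dataclass
class TrainTestResult:
    panel: set[str]
    test_accuracy: float
    records: pd.DataFrame


def tres_train_test(ds: GenotypeDataset, split_fraction: float = 0.5,
                    seed: int = 0, top_n: int = 200,
                    criterion: str = "frequency") -> TrainTestResult:
    """Build the multi-metric panel on a training split, assign the test half."""
    tr_idx, te_idx = stratified_split(ds, split_fraction, seed)
    train = ds.subset(sample_idx=tr_idx)
    test = ds.subset(sample_idx=te_idx)
    panel = tres_panel(train, top_n=top_n)
    if not panel:
        return TrainTestResult(panel=panel, test_accuracy=np.nan,
                               records=pd.DataFrame())
    keep = np.isin(np.array(ds.snp_ids), sorted(panel))
    recs = assign_and_detect_migrants(
        train.subset(marker_idx=keep), criterion=criterion,
        query=test.subset(marker_idx=keep))
    acc = float((recs["assigned_breed"] == recs["true_breed"]).mean())
    return TrainTestResult(panel=panel, test_accuracy=acc, records=recs)


def consensus_panel(fst_set: set[str], tres_all: set[str],
                    tres_tt: set[str]) -> dict:
    """Three-way intersection plus pairwise overlap counts (Venn analogue)."""
    return {
        "consensus": fst_set & tres_all & tres_tt,
        "n_fst": len(fst_set), "n_tres_all": len(tres_all),
        "n_tres_tt": len(tres_tt),
        "fst_and_tres_all": len(fst_set & tres_all),
        "fst_and_tres_tt": len(fst_set & tres_tt),
        "tres_all_and_tres_tt": len(tres_all & tres_tt),
        "three_way": len(fst_set & tres_all & tres_tt),
        "union": len(fst_set | tres_all | tres_tt),
    }


# ---------------------------------------------------------------------------
# likelihood criteria
# ---------------------------------------------------------------------------

ZERO_FREQ_SUB = 0.01  # GeneClass2 convention for unseen alleles


def likelihood_frequency(dosage_row: np.ndarray, freqs: np.ndarray) -> float:
    """log10 multilocus HWE genotype likelihood under breed allele freqs.

    ``freqs`` is the counted-allele frequency per panel SNP; frequencies of 0
    (or 1, for the other allele) are replaced by the GeneClass 0.01 floor.
    Missing genotypes are skipped.
    """
    called = dosage_row != MISSING
    if not called.any():
        raise ValueError("individual missing at every panel SNP")
    d = dosage_row[called].astype(float)
    p = np.asarray(freqs, dtype=float)[called]
    p = np.clip(p, ZERO_FREQ_SUB, 1.0 - ZERO_FREQ_SUB)
    probs = np.where(d == 2, p**2, np.where(d == 1, 2 * p * (1 - p), (1 - p) ** 2))
    return float(np.log10(probs).sum())


def likelihood_bayesian(dosage_row: np.ndarray, counts_b: np.ndarray,
                        counts_total: np.ndarray) -> float:
    """log10 Rannala–Mountain posterior-predictive genotype likelihood.

    With reference-allele counts (n_b of the counted allele out of n total
    allele copies) and a Dirichlet(1/2, 1/2) prior, the two alleles of the
    query genotype are drawn sequentially with posterior updating:
    hom-b: (n_b+1/2)(n_b+3/2)/((n+1)(n+2)); hom-a analogous;
    het: 2 (n_b+1/2)(n_a+1/2)/((n+1)(n+2)).
    """
    called = dosage_row != MISSING
    if not called.any():
        raise ValueError("individual missing at every panel SNP")
    d = dosage_row[called].astype(float)
    nb = np.asarray(counts_b, dtype=float)[called]
    n = np.asarray(counts_total, dtype=float)[called]
    na = n - nb
    denom = (n + 1.0) * (n + 2.0)
    hom_b = (nb + 0.5) * (nb + 1.5) / denom
    hom_a = (na + 0.5) * (na + 1.5) / denom
    het = 2.0 * (nb + 0.5) * (na + 0.5) / denom
    probs = np.where(d == 2, hom_b, np.where(d == 1, het, hom_a))
    return float(np.log10(probs).sum())


def _breed_counts(ds: GenotypeDataset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(counted-allele copies, total called copies) per SNP for each breed."""
    out = {}
    for b in sorted(set(ds.breeds)):
        d = ds.subset_breed(b).dosage
        called = d != MISSING
        out[b] = (np.where(called, d, 0).sum(axis=0).astype(float),
                  2.0 * called.sum(axis=0).astype(float))
    return out


def _loglik_for(dosage_row, breed, counts, criterion, exclude_row=None):
    nb, n = counts[breed]
    if exclude_row is not None:  # leave-one-out: remove the individual itself
        called = exclude_row != MISSING
        nb = nb - np.where(called, exclude_row, 0)
        n = n - 2.0 * called
    if criterion == "frequency":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, nb / n, 0.5)
        return likelihood_frequency(dosage_row, p)
    elif criterion == "bayesian":
        return likelihood_bayesian(dosage_row, nb, n)
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# Monte Carlo exclusion and assignment
# ---------------------------------------------------------------------------

def monte_carlo_exclusion(observed_loglik: float, freqs: np.ndarray,
                          criterion: str = "frequency",
                          counts_total: np.ndarray | None = None,
                          n_sim: int = 1000, seed: int = 0) -> float:
    """Paetkau resampling exclusion p-value for one individual vs one breed.

    ``n_sim`` multilocus genotypes are simulated by drawing two alleles per
    panel SNP from the breed frequencies; the p-value is the smoothed rank
    (count(L_sim <= L_obs) + 1)/(n_sim + 1), so p > 0 always.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    sims = rng.binomial(2, np.clip(freqs, 0, 1), size=(n_sim, freqs.size))
    if criterion == "frequency":
        ll = np.array([likelihood_frequency(row.astype(np.int8), freqs)
                       for row in sims])
    else:
        if counts_total is None:
            counts_total = np.full(freqs.size, 2.0 * 50)
        nb = freqs * counts_total
        ll = np.array([likelihood_bayesian(row.astype(np.int8), nb, counts_total)
                       for row in sims])
    return float(((ll <= observed_loglik + 1e-12).sum() + 1) / (n_sim + 1))


def assign_and_detect_migrants(reference: GenotypeDataset,
                               criterion: str = "frequency",
                               query: GenotypeDataset | None = None,
                               leave_one_out: bool = True,
                               exclusion_n_sim: int = 0,
                               exclusion_alpha: float = 0.001,
                               seed: int = 0) -> pd.DataFrame:
    """Assign each (query or reference) individual to its most likely breed.

    Returns one row per individual with per-breed log10 likelihoods, the
    normalized assignment probability, the assigned breed (ties broken by
    breed label order and flagged), the migrant statistic
    log10(L_home) - log10(L_max), and — when ``exclusion_n_sim`` > 0 —
    Paetkau exclusion p-values per breed.
    """
    breeds = sorted(set(reference.breeds))
    if len(breeds) < 2:
        raise ValueError("need at least two reference breeds")
    counts = _breed_counts(reference)
    self_assign = query is None
    cohort = reference if self_assign else query
    rows = []
    rng = np.random.default_rng(seed)
    for i, s in enumerate(cohort.samples):
        drow = cohort.dosage[i]
        lls = {}
        for b in breeds:
            loo = (drow if (self_assign and leave_one_out and s.breed == b)
                   else None)
            lls[b] = _loglik_for(drow, b, counts, criterion, exclude_row=loo)
        llvec = np.array([lls[b] for b in breeds])
        rel = 10.0 ** (llvec - llvec.max())
        probs = rel / rel.sum()
        best = int(np.argmax(llvec))
        tie = bool((llvec == llvec[best]).sum() > 1)
        home = s.breed if s.breed in breeds else breeds[best]
        row = {"sample_id": s.sample_id, "true_breed": s.breed,
               "assigned_breed": breeds[best], "tie": tie,
               "migrant_statistic": lls[home] - llvec.max()}
        for b, pr in zip(breeds, probs):
            row[f"loglik_{b}"] = lls[b]
            row[f"prob_{b}"] = float(pr)
        if exclusion_n_sim > 0:
            for b in breeds:
                nb, n = counts[b]
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = np.where(n > 0, nb / n, 0.5)
                pval = monte_carlo_exclusion(
                    lls[b], p, criterion=criterion, counts_total=n,
                    n_sim=exclusion_n_sim,
                    seed=int(rng.integers(2**31 - 1)))
                row[f"exclusion_p_{b}"] = pval
                row[f"excluded_{b}"] = pval < exclusion_alpha
        rows.append(row)
    return pd.DataFrame(rows)
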
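"""Sample- and SNP-level quality control.

Filter chain: samples are dropped first on call rate, then SNPs in a fixed
order — unmapped, sex-linked, call rate, MAF, HWE — with each excluded SNP
attributed to the first filter it fails.  Boundary conventions: a SNP is
excluded when MAF < maf_min (strict), call rate < call_rate_min (strict), or
HWE p <= hwe_p_max (inclusive).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import MISSING, GenotypeDataset


@dataclasses.dataclass
class QCThresholds:
    sample_call_rate_min: float = 0.9    # keep samples with rate > this
    snp_call_rate_min: float = 0.98      # exclude SNPs with rate < this
    maf_min: float = 0.01                # exclude SNPs with MAF < this
    hwe_p_max: float = 1e-6              # exclude SNPs with p <= this
    sex_chromosomes: tuple[str, ...] = ("X", "Y", "XY", "MT", "30", "31", "32", "33")
    hwe_pooled: bool = True              # HWE on the pooled cohort


@dataclasses.dataclass
class QCReport:
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    excluded_samples_call_rate: int
    excluded_unmapped: int
    excluded_sex_linked: int
    excluded_snp_call_rate: int
    excluded_maf: int
    excluded_hwe: int
    thresholds: QCThresholds

    @property
    def n_snps_excluded(self) -> int:
        return (self.excluded_unmapped + self.excluded_sex_linked
                + self.excluded_snp_call_rate + self.excluded_maf
                + self.excluded_hwe)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_snps_excluded"] = self.n_snps_excluded
        return d


def sample_call_rates(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per sample."""
    if ds.n_markers == 0:
        raise ValueError("empty dataset")
    return (ds.dosage != MISSING).mean(axis=1)


def snp_call_rates(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per SNP."""
    if ds.n_samples == 0:
        raise ValueError("empty dataset")
    return (ds.dosage != MISSING).mean(axis=0)


def allele_freq(ds: GenotypeDataset) -> np.ndarray:
    """Frequency of the counted allele per SNP (NaN where all-missing)."""
    called = ds.dosage != MISSING
    n_called = called.sum(axis=0)
    tot = np.where(called, ds.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, tot / (2.0 * n_called), np.nan)


def minor_allele_freq(ds: GenotypeDataset) -> np.ndarray:
    """Per-SNP minor allele frequency; NaN for all-missing SNPs."""
    p = allele_freq(ds)
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact test for Hardy–Weinberg equilibrium.

    Conditional on the observed allele counts, the heterozygote count follows
    a hypergeometric-type distribution; the p-value sums the probabilities of
    all heterozygote counts no more probable than the observed one.  Computed
    with the standard mid-free recurrence over het counts.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het  # rare-allele copies
    # het counts share parity with n_rare and range up to min(n_rare, 2n-n_rare)
    het_max = min(n_rare, 2 * n - n_rare)
    probs = np.zeros(het_max + 1)
    # start at the largest admissible het count and recurse downward
    h = het_max if het_max % 2 == n_rare % 2 else het_max - 1
    probs[h] = 1.0
    cur = h
    while cur > 1:
        hom_r = (n_rare - cur) // 2
        hom_c = n - cur - hom_r
        probs[cur - 2] = probs[cur] * cur * (cur - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        if probs[cur - 2] > 1e280:  # rescale to avoid overflow at large n
            probs /= probs[cur - 2]
        cur -= 2
    probs /= probs.sum()
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(ds: GenotypeDataset) -> np.ndarray:
    """HWE exact p per SNP on the pooled cohort; NaN where all-missing."""
    out = np.empty(ds.n_markers)
    d = ds.dosage
    for j in range(ds.n_markers):
        col = d[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_test(int((called == 0).sum()),
                                int((called == 1).sum()),
                                int((called == 2).sum()))
    return out


def apply_qc(ds: GenotypeDataset,
             thresholds: QCThresholds | None = None
             ) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC chain and return the filtered dataset with a report."""
    thr = thresholds or QCThresholds()
    n_samples_in, n_snps_in = ds.n_samples, ds.n_markers

    scr = sample_call_rates(ds)
    keep_s = scr > thr.sample_call_rate_min
    n_drop_samples = int((~keep_s).sum())
    ds = ds.subset(sample_idx=keep_s)
    if ds.n_samples == 0:
        raise ValueError("no samples survive QC")

    chrom = ds.chromosomes
    bp = ds.bp_positions
    status = np.zeros(ds.n_markers, dtype=np.int8)  # 0 keep; >0 filter index

    unmapped = (chrom == "0") | (bp == 0)
    status[unmapped & (status == 0)] = 1
    sex = np.isin(chrom, thr.sex_chromosomes)
    status[sex & (status == 0)] = 2
    cr = snp_call_rates(ds)
    status[(cr < thr.snp_call_rate_min) & (status == 0)] = 3
    maf = minor_allele_freq(ds)
    maf_fail = np.isnan(maf) | (maf < thr.maf_min)
    status[maf_fail & (status == 0)] = 4
    # HWE only needs evaluating on still-kept SNPs
    hwe_fail = np.zeros(ds.n_markers, dtype=bool)
    pend = np.flatnonzero(status == 0)
    if pend.size:
        sub = ds.subset(marker_idx=pend)
        pv = hwe_pvalues(sub)
        hwe_fail[pend] = np.isnan(pv) | (pv <= thr.hwe_p_max)
    status[hwe_fail & (status == 0)] = 5

    keep = status == 0
    out = ds.subset(marker_idx=keep)
    if out.n_markers == 0:
        raise ValueError("no SNPs survive QC")
    report = QCReport(
        n_samples_in=n_samples_in, n_samples_out=ds.n_samples,
        n_snps_in=n_snps_in, n_snps_out=out.n_markers,
        excluded_samples_call_rate=n_drop_samples,
        excluded_unmapped=int((status == 1).sum()),
        excluded_sex_linked=int((status == 2).sum()),
        excluded_snp_call_rate=int((status == 3).sum()),
        excluded_maf=int((status == 4).sum()),
        excluded_hwe=int((status == 5).sum()),
        thresholds=thr)
    return out, report
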
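"""Runs of homozygosity: sliding-window detection, F_ROH and summaries.

Detection follows PLINK's --homozyg scanning-window semantics: windows of a
fixed SNP count slide along each chromosome; a window is called homozygous
when it contains at most ``window_max_het`` heterozygous and at most
``window_max_missing`` missing calls; each SNP's hit rate is the fraction of
overlapping windows called homozygous; SNPs at or above the hit-rate
threshold are run-eligible; maximal eligible stretches are trimmed to start
and end on homozygous called SNPs, split at large inter-SNP gaps, and kept if
they satisfy the SNP-count, physical-length and SNP-density minima.

Segment length is end_bp - start_bp (PLINK kb-report convention).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

MB = 1_000_000

#: the six AdaptMap-style length classes (left-closed bounds, Mbp)
LENGTH_CLASSES = ((0, 3), (3, 5), (5, 10), (10, 20), (20, 30), (30, float("inf")))
LENGTH_CLASS_LABELS = ("<3", "3-5", "5-10", "10-20", "20-30", ">30")


@dataclasses.dataclass
class ROHParams:
    min_length_bp: int = 1_000_000
    window_snps: int = 15
    window_max_het: int = 1
    window_max_missing: int = 1
    window_hit_threshold: float = 0.05
    min_snps_in_roh: int = 15
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 50_000

    def __post_init__(self):
        if self.window_max_het >= self.window_snps:
            raise ValueError("window_max_het must be < window_snps")
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0 and f.name != "window_max_het" \
                    and f.name != "window_max_missing":
                raise ValueError(f"{f.name} must be positive")


@dataclasses.dataclass
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclasses.dataclass
class FrohRecord:
    sample_id: str
    froh_total: float
    froh_lt10mb: float
    froh_10_20mb: float
    froh_gt20mb: float
    denominator_bp: int


def _eligible_snps(is_het: np.ndarray, is_miss: np.ndarray,
                   params: ROHParams) -> np.ndarray:
    """Hit-rate scan for one sample on one chromosome (ordered SNP vectors).
    Returns the boolean run-eligibility per SNP."""
    m = is_het.size
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    het_c = np.convolve(is_het.astype(int), np.ones(w, dtype=int), "valid")
    mis_c = np.convolve(is_miss.astype(int), np.ones(w, dtype=int), "valid")
    win_ok = (het_c <= params.window_max_het) & (mis_c <= params.window_max_missing)
    # SNP j overlaps windows starting in [j-w+1, j] clipped to [0, m-w]
    ok_cum = np.concatenate([[0], np.cumsum(win_ok)])
    starts = np.maximum(np.arange(m) - w + 1, 0)
    ends = np.minimum(np.arange(m), m - w)
    n_windows = ends - starts + 1
    n_ok = ok_cum[ends + 1] - ok_cum[starts]
    return n_ok / n_windows >= params.window_hit_threshold


def detect_roh(ds: GenotypeDataset, params: ROHParams | None = None
               ) -> list[ROHSegment]:
    """Detect ROH segments for every sample; markers must be position-sorted."""
    params = params or ROHParams()
    if not ds.markers_sorted():
        raise ValueError("markers must be sorted by (chromosome, bp)")
    chrom = ds.chromosomes
    bp = ds.bp_positions
    segments: list[ROHSegment] = []
    chrom_slices = _chromosome_slices(chrom)
    for i, s in enumerate(ds.samples):
        row = ds.dosage[i]
        for c, sl in chrom_slices:
            d = row[sl]
            pos = bp[sl]
            is_miss = d == MISSING
            is_het = d == 1
            elig = _eligible_snps(is_het, is_miss, params)
            for a, b in _runs(elig):
                segments.extend(_finalize_run(
                    s.sample_id, c, pos, is_het, is_miss, a, b, params))
    return segments


def _chromosome_slices(chrom: np.ndarray) -> list[tuple[str, slice]]:
    out = []
    start = 0
    for j in range(1, len(chrom) + 1):
        if j == len(chrom) or chrom[j] != chrom[start]:
            out.append((chrom[start], slice(start, j)))
            start = j
    return out


def _runs(mask: np.ndarray):
    """Yield (start, end_exclusive) of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b)


def _finalize_run(sample_id, chromosome, pos, is_het, is_miss, a, b,
                  params: ROHParams) -> list[ROHSegment]:
    """Trim a candidate stretch to homozygous called ends, split at gaps,
    apply length / count / density filters."""
    hom = ~is_het & ~is_miss
    idx = np.arange(a, b)[hom[a:b]]  # homozygous called SNPs inside the run
    segs = []
    if idx.size == 0:
        return segs
    # split where inter-SNP gap exceeds max_gap (gaps measured on the SNPs
    # actually inside the run, matching PLINK's gap rule)
    breaks = np.flatnonzero(np.diff(pos[idx]) > params.max_gap_bp)
    pieces = np.split(idx, breaks + 1)
    for piece in pieces:
        if piece.size == 0:
            continue
        lo, hi = int(piece[0]), int(piece[-1])
        # count all SNPs between the trimmed ends (hets inside stay counted)
        n_snps = hi - lo + 1
        start_bp, end_bp = int(pos[lo]), int(pos[hi])
        length = end_bp - start_bp
        if n_snps < params.min_snps_in_roh:
            continue
        if length < params.min_length_bp:
            continue
        if length / n_snps > params.min_density_bp_per_snp:
            continue
        segs.append(ROHSegment(sample_id=sample_id, chromosome=chromosome,
                               start_bp=start_bp, end_bp=end_bp, n_snps=n_snps))
    return segs


def autosome_coverage_bp(ds: GenotypeDataset) -> int:
    """SNP-covered genome length: sum over chromosomes of (last - first bp)."""
    total = 0
    chrom = ds.chromosomes
    bp = ds.bp_positions
    for _, sl in _chromosome_slices(chrom):
        p = bp[sl]
        total += int(p[-1] - p[0])
    if total <= 0:
        raise ValueError("empty marker map")
    return total


def froh(segments: list[ROHSegment], ds: GenotypeDataset) -> list[FrohRecord]:
    """Per-sample genomic inbreeding from ROH: summed segment length over the
    SNP-covered autosome length, with <10 Mb / 10-20 Mb / >20 Mb bins."""
    denom = autosome_coverage_bp(ds)
    by_sample: dict[str, list[ROHSegment]] = defaultdict(list)
    for seg in segments:
        by_sample[seg.sample_id].append(seg)
    records = []
    for s in ds.samples:
        segs = by_sample.get(s.sample_id, [])
        lt = sum(x.length_bp for x in segs if x.length_bp < 10 * MB)
        mid = sum(x.length_bp for x in segs if 10 * MB <= x.length_bp < 20 * MB)
        gt = sum(x.length_bp for x in segs if x.length_bp >= 20 * MB)
        records.append(FrohRecord(
            sample_id=s.sample_id,
            froh_total=(lt + mid + gt) / denom,
            froh_lt10mb=lt / denom, froh_10_20mb=mid / denom,
            froh_gt20mb=gt / denom, denominator_bp=denom))
    return records


def roh_class_spectrum(segments: list[ROHSegment]) -> pd.DataFrame:
    """Counts and length-share of segments in the six length classes.

    ``freq`` is each class's summed length relative to the total ROH length
    in Mbp (the AdaptMap-style normalization); ``count`` the raw number.
    """
    lengths_mb = np.array([s.length_bp / MB for s in segments])
    total = lengths_mb.sum()
    rows = []
    for (lo, hi), label in zip(LENGTH_CLASSES, LENGTH_CLASS_LABELS):
        inside = (lengths_mb >= lo) & (lengths_mb < hi)
        rows.append({"class_mbp": label, "count": int(inside.sum()),
                     "total_mbp": float(lengths_mb[inside].sum()),
                     "freq": float(lengths_mb[inside].sum() / total) if total else 0.0})
    return pd.DataFrame(rows)


def avg_pct_roh_per_chromosome(segments: list[ROHSegment],
                               ds: GenotypeDataset) -> pd.DataFrame:
    """Average percentage of a chromosome covered by ROH among the animals
    that have one there: (sum ROH Mbp / N) / chrom length Mbp * 100."""
    chrom = ds.chromosomes
    bp = ds.bp_positions
    rows = []
    for c, sl in _chromosome_slices(chrom):
        length_mb = (bp[sl][-1] - bp[sl][0]) / MB
        segs = [s for s in segments if s.chromosome == c]
        animals = {s.sample_id for s in segs}
        n = len(animals)
        tot_mb = sum(s.length_bp for s in segs) / MB
        pct = (tot_mb / n) / length_mb * 100.0 if n else 0.0
        rows.append({"chromosome": c, "n_animals_with_roh": n,
                     "total_roh_mbp": tot_mb, "chrom_length_mbp": length_mb,
                     "avg_pct": pct, "no_roh": n == 0})
    return pd.DataFrame(rows)


def snp_in_roh_incidence(segments: list[ROHSegment], ds: GenotypeDataset,
                         breed: str | None = None) -> np.ndarray:
    """Per-SNP percentage of (breed) animals whose ROH cover its position."""
    if breed is not None:
        ids = {s.sample_id for s in ds.samples if s.breed == breed}
    else:
        ids = {s.sample_id for s in ds.samples}
    n = len(ids)
    counts = np.zeros(ds.n_markers)
    chrom = ds.chromosomes
    bp = ds.bp_positions
    for seg in segments:
        if seg.sample_id not in ids:
            continue
        inside = (chrom == seg.chromosome) & (bp >= seg.start_bp) & (bp <= seg.end_bp)
        counts += inside
    return 100.0 * counts / n if n else counts


def segments_table(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id, "chromosome": s.chromosome,
        "start_bp": s.start_bp, "end_bp": s.end_bp, "n_snps": s.n_snps,
        "length_kb": s.length_bp / 1000.0} for s in segments])
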
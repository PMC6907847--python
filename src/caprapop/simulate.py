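"""Synthetic two-breed genotype simulator with known truth.

Population allele frequencies follow the Balding–Nichols model: an ancestral
frequency p is drawn per SNP, and each population's frequency comes from
Beta(p(1-F)/F, (1-p)(1-F)/F), giving E[p_i] = p and Var[p_i] = p(1-p)F so the
divergence parameter F is the expected Weir–Cockerham FST.  Genotypes are
binomial draws given each individual's ancestry-weighted frequency; sites are
independent given ancestry (no background LD).  Autozygosity is injected as
explicit runs-of-homozygosity segments whose exact spans are recorded as
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import MISSING, GenotypeDataset, MarkerRecord, SampleRecord


@dataclasses.dataclass
class RohSpec:
    """Per-sample autozygosity to inject: total target fraction of the genome
    in ROH and the mean segment length (bp, exponential-ish around the mean)."""
    target_froh: float = 0.0
    mean_segment_bp: float = 5_000_000.0
    min_segment_bp: float = 1_500_000.0


@dataclasses.dataclass
class SimulationConfig:
    """Study-design knobs for the two-breed synthetic cohort.

    Defaults emulate the study design this package targets: two goat breeds
    (32 and 40 does) genotyped on a ~50K chip over 29 autosomes, weak
    divergence (FST ~ 0.04), a handful of admixed individuals, and light
    missingness.  n_snps/n_chromosomes default desk-scale; the chip-scale
    values are a config away.
    """

    n_pops: int = 2
    samples_per_pop: tuple[int, ...] = (32, 40)
    n_snps: int = 5_000
    n_chromosomes: int = 29
    chrom_length_bp: int = 100_000_000
    target_fst: float = 0.04
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    admixed_spec: tuple[tuple[int, tuple[float, ...]], ...] = ()
    roh_spec: dict[str, RohSpec] = dataclasses.field(default_factory=dict)
    missing_rate: float = 0.0
    # heterozygous sites delimiting each injected ROH on either side; two
    # (one more than the detector's per-window het allowance) make the span
    # boundary identifiable — without them the apparent tract extends into
    # chance homozygosity, a property of the data rather than the detector
    roh_boundary_hets: int = 2
    pop_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        for _, props in self.admixed_spec:
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("admixture proportions must sum to 1")
        if self.pop_names is None:
            self.pop_names = tuple(f"POP{k+1}" for k in range(self.n_pops))


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated dataset."""
    pop_allele_freqs: np.ndarray          # pops x SNPs
    ancestry_Q: np.ndarray                # samples x pops
    injected_segments: list               # of roh.ROHSegment
    realized_fst: float

    def to_json(self, path: str | Path) -> None:
        obj = {
            "ancestry_Q": self.ancestry_Q.tolist(),
            "realized_fst": self.realized_fst,
            "injected_segments": [dataclasses.asdict(s) for s in self.injected_segments],
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def simulate_population_freqs(cfg: SimulationConfig,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-population allele frequencies under Balding–Nichols.

    Ancestral frequencies are uniform on the MAF range mirrored about 0.5
    (so the counted allele is equally likely to be minor or major).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    F = cfg.target_fst
    if F <= 0:
        raise ValueError("degenerate divergence parameter F = 0")
    lo, hi = cfg.ancestral_maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_snps)
    flip = rng.random(cfg.n_snps) < 0.5
    p_anc = np.where(flip, 1.0 - maf, maf)
    scale = (1.0 - F) / F
    freqs = rng.beta(np.maximum(p_anc * scale, 1e-12),
                     np.maximum((1.0 - p_anc) * scale, 1e-12),
                     size=(cfg.n_pops, cfg.n_snps))
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


def _marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> list[MarkerRecord]:
    """SNP positions uniform per chromosome, then sorted; SNPs split as evenly
    as possible across chromosomes."""
    base, extra = divmod(cfg.n_snps, cfg.n_chromosomes)
    markers: list[MarkerRecord] = []
    idx = 0
    for c in range(1, cfg.n_chromosomes + 1):
        k = base + (1 if c <= extra else 0)
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp, size=k, dtype=np.int64))
        while pos.size < k:  # top up duplicate draws
            more = rng.integers(1, cfg.chrom_length_bp, size=k - pos.size,
                                dtype=np.int64)
            pos = np.unique(np.concatenate([pos, more]))
        for p in pos:
            markers.append(MarkerRecord(chromosome=str(c), snp_id=f"snp{idx}",
                                        genetic_pos=0.0, bp_pos=int(p),
                                        allele_a="A", allele_b="B"))
            idx += 1
    return markers


def _ancestry_matrix(cfg: SimulationConfig) -> tuple[np.ndarray, list[SampleRecord]]:
    rows: list[np.ndarray] = []
    samples: list[SampleRecord] = []
    for k, n in enumerate(cfg.samples_per_pop):
        q = np.zeros(cfg.n_pops)
        q[k] = 1.0
        for i in range(n):
            rows.append(q.copy())
            samples.append(SampleRecord(
                sample_id=f"{cfg.pop_names[k]}_{i+1}", breed=cfg.pop_names[k],
                farm=f"farm{k+1}", sex="2", phenotype="-9"))
    adm_idx = 0
    for count, props in cfg.admixed_spec:
        q = np.asarray(props, dtype=float)
        home = int(np.argmax(q))
        for _ in range(count):
            adm_idx += 1
            rows.append(q.copy())
            samples.append(SampleRecord(
                sample_id=f"ADM_{adm_idx}", breed=cfg.pop_names[home],
                farm="farm_adm", sex="2", phenotype="-9"))
    return np.vstack(rows), samples


def simulate_genotypes(cfg: SimulationConfig,
                       freqs: np.ndarray | None = None
                       ) -> tuple[GenotypeDataset, SimulationTruth]:
    """Simulate the full cohort: genotypes, ROH injection, missingness.

    Returns the dataset plus a :class:`SimulationTruth` holding the population
    frequencies, the ancestry matrix Q, the exact injected ROH spans and the
    realized (Hudson-style ratio-of-averages) FST between the first two
    populations' frequency draws.
    """
    from .roh import ROHSegment  # local import to avoid cycle

    rng = np.random.default_rng(cfg.seed)
    if freqs is None:
        freqs = simulate_population_freqs(cfg, rng)
    markers = _marker_map(cfg, rng)
    Q, samples = _ancestry_matrix(cfg)
    n = len(samples)
    # per-individual expected allele frequency at each SNP
    indiv_p = Q @ freqs                       # n x m
    dosage = rng.binomial(2, indiv_p).astype(np.int8)

    chrom = np.array([m.chromosome for m in markers])
    bp = np.array([m.bp_pos for m in markers], dtype=np.int64)

    injected: list[ROHSegment] = []
    for sid, spec in cfg.roh_spec.items():
        i = next((k for k, s in enumerate(samples) if s.sample_id == sid), None)
        if i is None:
            raise ValueError(f"roh_spec names unknown sample {sid!r}")
        genome_bp = cfg.n_chromosomes * cfg.chrom_length_bp
        target_bp = spec.target_froh * genome_bp
        placed = 0.0
        used: dict[str, list[tuple[int, int]]] = {}
        guard = 0
        while placed < target_bp and guard < 1000:
            guard += 1
            length = rng.exponential(spec.mean_segment_bp)
            length = float(np.clip(length, spec.min_segment_bp,
                                   cfg.chrom_length_bp * 0.8))
            c = str(rng.integers(1, cfg.n_chromosomes + 1))
            start = int(rng.integers(1, cfg.chrom_length_bp - int(length)))
            end = start + int(length)
            if end > cfg.chrom_length_bp:
                raise ValueError("segment span exceeds chromosome")
            if any(start < e and end > s for s, e in used.get(c, [])):
                continue
            used.setdefault(c, []).append((start, end))
            mask = (chrom == c) & (bp >= start) & (bp <= end)
            if mask.sum() == 0:
                continue
            # homozygous-by-descent: one allele drawn per SNP, doubled
            p_seg = indiv_p[i, mask]
            dosage[i, mask] = 2 * rng.binomial(1, p_seg).astype(np.int8)
            # informative flanks: heterozygous delimiters just outside the span
            if cfg.roh_boundary_hets > 0:
                inside = np.flatnonzero(mask)
                on_chrom = np.flatnonzero(chrom == c)
                lo_pos = np.searchsorted(on_chrom, inside[0])
                hi_pos = np.searchsorted(on_chrom, inside[-1])
                left = on_chrom[max(lo_pos - cfg.roh_boundary_hets, 0):lo_pos]
                right = on_chrom[hi_pos + 1:hi_pos + 1 + cfg.roh_boundary_hets]
                dosage[i, left] = 1
                dosage[i, right] = 1
            injected.append(ROHSegment(sample_id=sid, chromosome=c,
                                       start_bp=start, end_bp=end,
                                       n_snps=int(mask.sum())))
            placed += length
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    realized = _hudson_fst(freqs[0], freqs[1]) if cfg.n_pops >= 2 else 0.0
    ds = GenotypeDataset(samples, markers, dosage)
    truth = SimulationTruth(pop_allele_freqs=freqs, ancestry_Q=Q,
                            injected_segments=injected, realized_fst=realized)
    return ds, truth


def _hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Ratio-of-averages Hudson FST between two frequency vectors (used only
    to report the divergence realized by the frequency draws)."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
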
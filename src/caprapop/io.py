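"""PLINK genotype I/O and the in-memory genotype data model.

Genotypes are stored as a samples x markers dosage matrix counting copies of
``allele_b`` (the second allele observed in file order), with ``MISSING = -1``
as sentinel.  PLINK text (.ped/.map) and binary SNP-major (.bed/.bim/.fam)
formats are supported for both reading and writing; breed/farm metadata come
from the .fam/.ped family-ID column or a sidecar TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01


class PlinkFormatError(ValueError):
    """Malformed PLINK file (ragged rows, bad magic bytes, >2 alleles...)."""


@dataclasses.dataclass
class MarkerRecord:
    """One SNP: map position plus the two observed allele codes.

    ``allele_b`` is the counted allele; ``"0"`` is the placeholder when a
    marker is monomorphic (only one allele ever observed) or fully missing.
    """

    chromosome: str
    snp_id: str
    genetic_pos: float
    bp_pos: int
    allele_a: str = "0"
    allele_b: str = "0"


@dataclasses.dataclass
class SampleRecord:
    """One individual with its breed/farm labels and .fam pass-through fields."""

    sample_id: str
    breed: str = ""
    farm: str = ""
    father: str = "0"
    mother: str = "0"
    sex: str = "0"
    phenotype: str = "-9"


class GenotypeDataset:
    """Samples x markers dosage matrix with marker map and sample metadata.

    Parameters
    ----------
    samples : list of SampleRecord
    markers : list of MarkerRecord
    dosage : int8 ndarray, shape (n_samples, n_markers)
        Copies of ``allele_b`` in {0, 1, 2} or ``MISSING`` (-1).
    """

    def __init__(self, samples: Sequence[SampleRecord],
                 markers: Sequence[MarkerRecord], dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers")
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        snps = [m.snp_id for m in markers]
        if len(set(snps)) != len(snps):
            raise ValueError("duplicate snp_id")
        self.samples = list(samples)
        self.markers = list(markers)
        self.dosage = dosage

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [m.snp_id for m in self.markers]

    @property
    def breeds(self) -> np.ndarray:
        return np.array([s.breed for s in self.samples])

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers])

    @property
    def bp_positions(self) -> np.ndarray:
        return np.array([m.bp_pos for m in self.markers], dtype=np.int64)

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with MISSING mapped to NaN."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        return d

    # -- subsetting ------------------------------------------------------

    def subset(self, sample_idx: np.ndarray | None = None,
               marker_idx: np.ndarray | None = None) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if mi.dtype == bool:
            mi = np.flatnonzero(mi)
        return GenotypeDataset(
            [self.samples[i] for i in si],
            [self.markers[j] for j in mi],
            self.dosage[np.ix_(si, mi)],
        )

    def subset_breed(self, breed: str) -> "GenotypeDataset":
        return self.subset(sample_idx=self.breeds == breed)

    def sort_markers(self) -> "GenotypeDataset":
        """Return a copy sorted by (chromosome, bp_pos); chromosome order is
        numeric where labels are numeric, lexicographic otherwise."""
        def key(m: MarkerRecord):
            c = m.chromosome
            return ((0, int(c), "") if c.isdigit() else (1, 0, c), m.bp_pos)
        order = sorted(range(self.n_markers), key=lambda j: key(self.markers[j]))
        return self.subset(marker_idx=np.array(order))

    def markers_sorted(self) -> bool:
        prev = None
        for m in self.markers:
            cur = (m.chromosome, m.bp_pos)
            if prev is not None and prev[0] == cur[0] and cur[1] < prev[1]:
                return False
            prev = cur
        return True

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (self.samples == other.samples and self.markers == other.markers
                and np.array_equal(self.dosage, other.dosage))

    def __repr__(self) -> str:
        return f"<GenotypeDataset {self.n_samples} samples x {self.n_markers} markers>"


# ---------------------------------------------------------------------------
# text format (.ped/.map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a PLINK .ped/.map pair.

    The counted allele (``allele_b``) at each marker is the second distinct
    allele in file order; "0 0" genotype pairs are missing.  The .ped FID
    column is used as the breed label.
    """
    markers = _read_map(map_path)
    m = len(markers)
    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    # first pass collects allele codes in observation order
    allele_order: list[list[str]] = [[] for _ in range(m)]
    raw_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * m}")
            samples.append(SampleRecord(
                sample_id=fields[1], breed=fields[0], father=fields[2],
                mother=fields[3], sex=fields[4], phenotype=fields[5]))
            geno = fields[6:]
            raw_rows.append(geno)
            for j in range(m):
                for a in (geno[2 * j], geno[2 * j + 1]):
                    if a != "0" and a not in allele_order[j]:
                        allele_order[j].append(a)
                        if len(allele_order[j]) > 2:
                            raise PlinkFormatError(
                                f"{ped_path}: >2 alleles at {markers[j].snp_id}")
    for j, obs in enumerate(allele_order):
        markers[j].allele_a = obs[0] if len(obs) >= 1 else "0"
        markers[j].allele_b = obs[1] if len(obs) >= 2 else "0"
    for geno in raw_rows:
        row = np.empty(m, dtype=np.int8)
        for j in range(m):
            a1, a2 = geno[2 * j], geno[2 * j + 1]
            if a1 == "0" or a2 == "0":
                row[j] = MISSING
            else:
                b = markers[j].allele_b
                row[j] = (a1 == b) + (a2 == b)
        rows.append(row)
    dosage = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    return GenotypeDataset(samples, markers, dosage)


def _read_map(map_path: str | Path) -> list[MarkerRecord]:
    markers = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise PlinkFormatError(f"{map_path}: line {lineno} too short")
            markers.append(MarkerRecord(
                chromosome=fields[0], snp_id=fields[1],
                genetic_pos=float(fields[2]), bp_pos=int(fields[3])))
    return markers


def write_plink_text(ds: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write .ped/.map.  Missing genotypes become "0 0"; the counted allele
    pairing is preserved so read->write->read round-trips."""
    prefix = Path(prefix)
    ped, mp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(mp, "w") as fh:
        for m in ds.markers:
            gp = int(m.genetic_pos) if m.genetic_pos == int(m.genetic_pos) else m.genetic_pos
            fh.write(f"{m.chromosome}\t{m.snp_id}\t{gp}\t{m.bp_pos}\n")
    with open(ped, "w") as fh:
        for i, s in enumerate(ds.samples):
            fields = [s.breed or "0", s.sample_id, s.father, s.mother, s.sex,
                      s.phenotype]
            for j, m in enumerate(ds.markers):
                d = ds.dosage[i, j]
                a, b = m.allele_a, m.allele_b
                if d == MISSING:
                    pair = ("0", "0")
                elif d == 0:
                    pair = (a, a)
                elif d == 1:
                    pair = (a, b)
                else:
                    pair = (b, b)
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")
    return ped, mp


# ---------------------------------------------------------------------------
# binary format (.bed/.bim/.fam), SNP-major
# ---------------------------------------------------------------------------

# 2-bit codes (low bits first within a byte): 00 hom allele_a, 01 missing,
# 10 het, 11 hom allele_b -> dosage of allele_b.
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink_binary(bed_path: str | Path, bim_path: str | Path,
                      fam_path: str | Path) -> GenotypeDataset:
    """Read a PLINK binary trio (SNP-major mode only)."""
    markers = []
    with open(bim_path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            markers.append(MarkerRecord(
                chromosome=f[0], snp_id=f[1], genetic_pos=float(f[2]),
                bp_pos=int(f[3]), allele_a=f[4], allele_b=f[5]))
    samples = []
    with open(fam_path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            samples.append(SampleRecord(
                sample_id=f[1], breed=f[0], father=f[2], mother=f[3],
                sex=f[4], phenotype=f[5]))
    n, m = len(samples), len(markers)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: sample-major mode (0x00) is unsupported")
    bpm = (n + 3) // 4  # bytes per marker
    if len(raw) - 3 != bpm * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bpm * m} payload bytes, got {len(raw) - 3}")
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpm)
    # unpack 2-bit codes, sample i in byte i//4 at bit offset 2*(i%4)
    codes = np.empty((m, bpm * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T
    # dosage counts allele_b: 00 = 2 copies allele_a = 0 copies allele_b
    return GenotypeDataset(samples, markers, dosage)


def write_plink_binary(ds: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write .bed (SNP-major, 4 genotypes/byte, zero-padded) + .bim/.fam."""
    prefix = Path(prefix)
    bed = prefix.with_suffix(".bed")
    bim = prefix.with_suffix(".bim")
    fam = prefix.with_suffix(".fam")
    n, m = ds.n_samples, ds.n_markers
    bpm = (n + 3) // 4
    codes = np.zeros((m, bpm * 4), dtype=np.uint8)
    dt = ds.dosage.T
    for d, c in _DOSAGE_TO_CODE.items():
        codes[:, :n][dt == d] = c
    packed = np.zeros((m, bpm), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
    with open(bim, "w") as fh:
        for mk in ds.markers:
            gp = int(mk.genetic_pos) if mk.genetic_pos == int(mk.genetic_pos) else mk.genetic_pos
            fh.write(f"{mk.chromosome}\t{mk.snp_id}\t{gp}\t{mk.bp_pos}"
                     f"\t{mk.allele_a}\t{mk.allele_b}\n")
    with open(fam, "w") as fh:
        for s in ds.samples:
            fh.write(f"{s.breed or '0'}\t{s.sample_id}\t{s.father}\t{s.mother}"
                     f"\t{s.sex}\t{s.phenotype}\n")
    return bed, bim, fam


def attach_metadata(ds: GenotypeDataset, tsv_path: str | Path) -> GenotypeDataset:
    """Attach breed (and optional farm) labels from a sidecar TSV with
    columns sample_id, breed[, farm]."""
    tab = pd.read_csv(tsv_path, sep="\t", dtype=str)
    cols = list(tab.columns)
    if len(cols) < 2:
        raise ValueError("metadata TSV needs at least sample_id and breed columns")
    tab = tab.set_index(cols[0])
    samples = []
    for s in ds.samples:
        rec = dataclasses.replace(s)
        if s.sample_id in tab.index:
            row = tab.loc[s.sample_id]
            rec.breed = str(row.iloc[0])
            if len(cols) > 2 and not pd.isna(row.iloc[1]):
                rec.farm = str(row.iloc[1])
        samples.append(rec)
    return GenotypeDataset(samples, ds.markers, ds.dosage.copy())
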
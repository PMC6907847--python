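import numpy as np
import pytest

from caprapop.io import GenotypeDataset, MarkerRecord, SampleRecord
from caprapop.simulate import SimulationConfig, simulate_genotypes


def make_dataset(dosage, bp=None, chrom=None, breeds=None, alleles=("A", "B")):
    """Build a small GenotypeDataset from a dosage matrix."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    bp = bp if bp is not None else np.arange(1, m + 1) * 1000
    chrom = chrom if chrom is not None else ["1"] * m
    breeds = breeds if breeds is not None else ["B1"] * n
    markers = [MarkerRecord(chromosome=str(chrom[j]), snp_id=f"m{j}",
                            genetic_pos=0.0, bp_pos=int(bp[j]),
                            allele_a=alleles[0], allele_b=alleles[1])
               for j in range(m)]
    samples = [SampleRecord(sample_id=f"s{i}", breed=breeds[i])
               for i in range(n)]
    return GenotypeDataset(samples, markers, dosage)


def random_dataset(rng, n=10, m=50, missing_rate=0.1):
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    miss = rng.random((n, m)) < missing_rate
    dosage[miss] = -1
    bp = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
    return make_dataset(dosage, bp=bp)


@pytest.fixture(scope="session")
def two_pop_f02():
    """Strongly diverged two-population cohort used across structure and
    panel tests (F = 0.2, 2,000 SNPs, 40+40 pure plus 10 half-admixed)."""
    cfg = SimulationConfig(n_snps=2000, samples_per_pop=(40, 40),
                           target_fst=0.2,
                           admixed_spec=((10, (0.5, 0.5)),), seed=42)
    return simulate_genotypes(cfg)
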
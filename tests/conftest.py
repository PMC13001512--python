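import numpy as np
import pytest

from g4chromatin.intervals import GenomeSpec, IntervalSet
from g4chromatin.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study used by most integration-level tests."""
    return SimConfig(
        seed=1234,
        n_chrom=2,
        chrom_size_bp=5_000_000,
        n_genes=300,
        n_atac_peaks=1200,
        n_g4_peaks=300,
        n_background_hits=200,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    size: int = 100_000,
    max_len: int = 2_000,
) -> IntervalSet:
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, size - length))
        rows.append((chrom, start, start + length, f"iv_{i}"))
    return IntervalSet.from_records(rows)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSpec:
    return GenomeSpec(("chr1", "chr2"), (1_000_000, 500_000))
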
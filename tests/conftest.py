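import numpy as np
import pytest

from mirkit.model import (
    DonorConfig,
    Layout,
    Pathway,
    RepairScenario,
)
from mirkit.risk import GenomeIntervals


@pytest.fixture
def ectopic_config() -> DonorConfig:
    return DonorConfig(layout=Layout.ECTOPIC_TRANS, flank3_homology_bp=70)


@pytest.fixture
def allelic_config() -> DonorConfig:
    return DonorConfig(layout=Layout.ALLELIC_INTERCHROMOSOMAL)


@pytest.fixture
def gene_conversion_scenario() -> RepairScenario:
    return RepairScenario(
        pathway=Pathway.MIR1,
        p_internal_repair={"gene_conversion_with_initiating_end": 1.0},
    )


def per_base_coverage(g: GenomeIntervals) -> int:
    """Brute-force covered-base count via boolean arrays (test oracle)."""
    total = 0
    for chrom, size in g.chrom_sizes.items():
        mask = np.zeros(size, dtype=bool)
        for a, b in g.intervals.get(chrom, ()):
            mask[a:b] = True
        total += int(mask.sum())
    return total


def random_genome(rng: np.random.Generator, max_len: int = 50_000,
                  max_intervals: int = 60) -> GenomeIntervals:
    """Random small genome with possibly-overlapping intervals."""
    n_chrom = int(rng.integers(1, 4))
    sizes = {
        f"chr{i}": int(rng.integers(1_000, max_len)) for i in range(n_chrom)
    }
    ivs = {}
    for chrom, size in sizes.items():
        n = int(rng.integers(0, max_intervals))
        pairs = []
        for _ in range(n):
            a = int(rng.integers(0, size - 1))
            b = int(rng.integers(a + 1, min(size, a + 2_000) + 1))
            pairs.append((a, min(b, size)))
        ivs[chrom] = pairs
    return GenomeIntervals(sizes, ivs)
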
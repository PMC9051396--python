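import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dmgcall.model import GeneAnnotation, GenomicInterval, Peak
from dmgcall.simulate import SimulationConfig, simulate_genome


@pytest.fixture
def small_annotation():
    """Five genes on two chromosomes with mixed strands."""
    return [
        GeneAnnotation("geneA", GenomicInterval("chr1", 10_000, 15_000), "+"),
        GeneAnnotation("geneB", GenomicInterval("chr1", 40_000, 43_000), "-"),
        GeneAnnotation("geneC", GenomicInterval("chr1", 80_000, 90_000), "+"),
        GeneAnnotation("geneD", GenomicInterval("chr2", 5_000, 9_000), "+"),
        GeneAnnotation("geneE", GenomicInterval("chr2", 50_000, 52_000), "-"),
    ]


@pytest.fixture
def tiny_sim_config():
    return SimulationConfig(
        seed=11, n_chroms=2, chrom_lengths=(2_000_000, 2_000_000), n_genes=100,
        age_groups=("13m",), peak_background_rate=1.0,
    )


@pytest.fixture
def tiny_annotation(tiny_sim_config):
    annotation, truth = simulate_genome(tiny_sim_config)
    return annotation


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000, max_width=5_000):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        peaks.append(
            Peak(
                GenomicInterval(str(rng.choice(chroms)), start, start + width),
                "s",
                float(rng.uniform(0, 10)),
            )
        )
    return peaks
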
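import numpy as np
import pytest

from hapcontext.phasing import PhasedBlock, PhasedSNP
from hapcontext.simulate import (
    BiasRegionSpec,
    GeneSpec,
    MethylationRegionSpec,
    SimulationConfig,
    SVClusterSpec,
    simulate_tumor,
)


def make_block(pattern, chrom="chr1", block_id=1, start=100, step=100):
    """Blocks for phasing-comparison tests: ``pattern`` is a 0/1 sequence,
    1 meaning the SNP's alleles are exchanged relative to the base block."""
    snps = []
    for i, flip in enumerate(pattern):
        hp1, hp2 = ("A", "G") if not flip else ("G", "A")
        snps.append(
            PhasedSNP(chrom, start + i * step, "A", "G", block_id, hp1, hp2)
        )
    return PhasedBlock(chrom, block_id, snps)


@pytest.fixture(scope="session")
def demo_config():
    return SimulationConfig(
        genome_length=500_000,
        depth=20,
        seed=7,
        bias_regions=(
            BiasRegionSpec("chr1", 100_001, 200_000, 1, 0.95, 30,
                           "apobec_like_synthetic"),
        ),
        sv_clusters=(SVClusterSpec("chr1", 300_001, 450_000, 1, 12, 6),),
        methylation_regions=(
            MethylationRegionSpec("chr1", 50_001, 80_000, 0.9, 0.1),
        ),
        genes=(
            GeneSpec("G1", "chr1", 210_001, 260_000, 40, 10, 25, 25),
        ),
    )


@pytest.fixture(scope="session")
def demo_case(demo_config):
    """One mid-size synthetic tumor shared across read-level tests."""
    return simulate_tumor(demo_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
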
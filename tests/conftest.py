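import numpy as np
import pytest

from inbredscape.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def bundle():
    """A small simulated bundle shared by read-only tests: two TE bursts,
    two full proviruses plus fragments, a handful of genes."""
    cfg = SimulationConfig(
        genome_length=500_000,
        mean_block_length=50_000,
        gene_count=4,
        te_bursts=[("famA", 60, 0.10, 0.02), ("famB", 60, 0.20, 0.02)],
        provirus_count=2,
        fragment_count=6,
        seed=11,
    )
    return simulate_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
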
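import numpy as np
import pytest

from tedepth.simulate import FamilySpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_config():
    """One 10-copy identical family in 95 kb of background; deterministic tiling."""
    return SimulationConfig(
        background_length=95_000,
        families=(FamilySpec("Gypsy_fam1", "Gypsy", copy_number=10, divergence=0.0, consensus_length=5000),),
        coverage=10.0,
        fragment_length=10,
        tiling_mode="exact",
        seed=11,
        n_genes=50,
        gene_span_range=(1200, 1500),
        min_gap=100,
    )
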
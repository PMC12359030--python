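import numpy as np
import pytest

from readcoal import SimulationConfig, build_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def tree_b():
    return build_preset("B", 0.01)


@pytest.fixture
def tree_b_im():
    return build_preset("B-IM", 0.01)


@pytest.fixture
def small_config():
    return SimulationConfig(
        loci=3,
        samples_per_species=1,
        sites=120,
        error_rate=0.01,
        mean_depth=5.0,
        seed=1234,
        error_mode="both-err",
    )
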
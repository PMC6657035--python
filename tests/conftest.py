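import numpy as np
import pytest

from ewasforest import RFConfig, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort configuration used across test modules."""
    return SimulationConfig(
        n_samples=240,
        n_cpgs=600,
        n_discriminating_cpgs_per_type=10,
        n_planted_cpgs=6,
        rng_seed=7,
        structure_seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def fast_rf():
    return RFConfig(ntree=150, rng_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
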
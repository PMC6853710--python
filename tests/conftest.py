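import numpy as np
import pytest

from scsomatic.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_tumor=12, n_normal=8, m_mut=10, m_null=300, mean_coverage=40.0, seed=101
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
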
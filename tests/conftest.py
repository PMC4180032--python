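import numpy as np
import pytest

from peamap.config import SimulationConfig
from peamap.simulate import simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete synthetic study shared across tests."""
    cfg = SimulationConfig(seed=7, n_contigs=70, n_markers_per_lg=10,
                           ril_pop_sizes=(80, 60), lg_length_cM=60.0)
    return simulate_study(cfg)
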
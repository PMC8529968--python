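import numpy as np
import pytest

from tmescope import SCSimConfig, simulate_cell_pool


@pytest.fixture(scope="session")
def small_pool():
    """5-type pool used across modules; small enough to keep tests fast."""
    cfg = SCSimConfig(n_types=5, n_genes=800, cells_per_type=80, markers_per_type=20, seed=1)
    return simulate_cell_pool(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
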
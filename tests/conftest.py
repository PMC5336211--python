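import numpy as np
import pytest

from glandabc.growth_model import GrowthParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Reduced growth model for fast end-to-end tests."""
    return GrowthParams(alpha=1.0, beta=0.2, r=0.8, n_csc=8, t3=5, n_fission_gens=4)


@pytest.fixture
def default_params():
    return GrowthParams(alpha=2.0, beta=0.1, r=0.8)
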
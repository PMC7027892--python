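import numpy as np
import pytest

from logimonod import BatchConditions, GrowthParameters


@pytest.fixture
def batch_params() -> GrowthParameters:
    """The shared batch parameter set (carrying capacity just below X_0 + Y*S_0)."""
    return GrowthParameters(mu_max=0.5, K_s=4.0, X_m=12.5, Y_xs=0.5)


@pytest.fixture
def batch_conditions() -> BatchConditions:
    return BatchConditions(X_0=0.25, S_0=25.0)


@pytest.fixture
def cstr_params() -> GrowthParameters:
    """The shared chemostat parameter set, high-yield variant (Y_xs = 0.8)."""
    return GrowthParameters(mu_max=1.6, K_s=1.0, X_m=10.0, Y_xs=0.8)


@pytest.fixture
def feed_substrate() -> float:
    return 20.0


@pytest.fixture
def time_grid() -> np.ndarray:
    return np.linspace(0.0, 25.0, 100)
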
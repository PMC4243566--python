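import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from skan import NetParams, SkanParams


@pytest.fixture
def params2() -> SkanParams:
    """Reference parameter set for a two-input neuron."""
    return SkanParams(n_inputs=2)


@pytest.fixture
def params4() -> SkanParams:
    return SkanParams(n_inputs=4)


@pytest.fixture
def net2() -> NetParams:
    return NetParams(n_neurons=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
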
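import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from wyckoff import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def common_contraction_params():
    """A shared-theta/lambda parameter set well inside the contraction regime."""
    return ModelParams.common(0.2, 0.0, u1=0.6, u2=0.3)


@pytest.fixture
def general_params():
    """A heterogeneous, non-contraction parameter set for generic checks."""
    theta = [0.8, 0.3, 0.55, 0.7, 0.25, 0.9, 0.4, 0.6]
    lam = [0.25, 0.0, 1.0, 0.5, 0.75, 0.1, 0.9, 0.3]
    return ModelParams(theta, lam, u1=0.7, u2=0.4)
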
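import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bicell import ModelParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def params() -> ModelParams:
    """Small, fast default parameter set for unit tests."""
    return ModelParams(n=50, cycles=20, d_scale=1000.0, r=0.5, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
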
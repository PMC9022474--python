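import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_wpli_stack(rng):
    """Stack of valid random symmetric wPLI-like matrices (n=20, R=10)."""
    n, R = 20, 10
    mats = rng.random((n, R, R))
    mats = (mats + mats.swapaxes(1, 2)) / 2
    for m in mats:
        np.fill_diagonal(m, 0)
    return np.clip(mats, 0.0, 1.0)
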
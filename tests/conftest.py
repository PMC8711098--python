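import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fixture():
    """Fast smooth-regression cohort for solver tests (n=60, d=3)."""
    from mlaprbfn import generate_multiview_fixture

    return generate_multiview_fixture(n=60, d=3, noise_sd=0.05, seed=0)
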
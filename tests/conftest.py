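import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def balanced_residuals(rng):
    """100 device-B-like residuals with balanced quarter labels."""
    resid = rng.normal(0.0, 0.95, 100)
    labels = np.tile(np.arange(4), 25)
    return resid, labels


@pytest.fixture
def small_fixture(rng):
    """40 residuals, 10 per quarter, for closed-form vs sampler checks."""
    resid = rng.normal(0.1, 0.9, 40)
    labels = np.repeat(np.arange(4), 10)
    return resid, labels
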
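import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_correlation():
    """Factory for random well-conditioned correlation matrices."""

    def make(K, seed, n_samples=None):
        r = np.random.default_rng(seed)
        n = n_samples or 3 * K
        return np.corrcoef(r.normal(size=(K, n)))

    return make
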
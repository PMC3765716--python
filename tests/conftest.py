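import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_point_prior():
    from ebdiff import MixingDistribution

    return MixingDistribution([1.0, 10.0], [0.5, 0.5])


def random_mixing(rng, max_points=8, lam_range=(0.2, 80.0)):
    """A random valid discrete prior for property tests."""
    from ebdiff import MixingDistribution

    k = int(rng.integers(1, max_points + 1))
    support = np.sort(rng.uniform(*lam_range, size=k))
    support = support + np.arange(k) * 1e-6  # ensure strict increase
    weights = rng.dirichlet(np.ones(k))
    return MixingDistribution(support, weights)
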
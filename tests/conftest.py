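import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ifpace import ControllerConfig, RuleBase, TermSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def terms():
    return TermSet.default()


@pytest.fixture(scope="session")
def rules():
    return RuleBase()


@pytest.fixture(scope="session")
def cfg():
    return ControllerConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ifn_pairs(rng, n):
    """Uniform sample of valid (mu, nu) pairs with mu + nu <= 1."""
    mu = rng.uniform(0.0, 1.0, n)
    nu = rng.uniform(0.0, 1.0, n) * (1.0 - mu)
    return mu, nu
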
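import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import weam

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
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_domain():
    """Small 10-class domain for experiment-level tests."""
    return weam.generate_domain(weam.DomainSpec(n=16, size=500, seed=3))


@pytest.fixture(scope="session")
def default_domain():
    """The study-scale domain (64 features, 7000 objects)."""
    return weam.generate_domain(weam.DomainSpec(seed=1))
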
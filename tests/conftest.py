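import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from parsebp import DecoySpec, ideal_duplex, make_ensemble

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def duplex16():
    """16-bp (32-nt) ideal A-form duplex and its designed pair list."""
    return ideal_duplex(16)


@pytest.fixture(scope="session")
def duplex8():
    return ideal_duplex(8)


@pytest.fixture(scope="session")
def graded_pool():
    """12-decoy pool in three noise tiers with ground-truth TM to reference."""
    return make_ensemble(DecoySpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
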
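import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beditscan.synthetic_data import make_default_sites

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sites():
    return {s.site_id: s for s in make_default_sites()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
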
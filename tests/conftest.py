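import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ballstick as bs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_scenario():
    """Default two-fiber voxel: S0=400, b=1500, d=1/1500, fibers at 60/120 deg."""
    truth, protocol = bs.make_scenario("paper-default-64")
    return truth, protocol


@pytest.fixture(scope="session")
def clean_signal(paper_scenario):
    truth, protocol = paper_scenario
    return bs.predict_signal(truth, protocol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
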
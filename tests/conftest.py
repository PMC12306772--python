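import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungscreen_cea import base_case_fixture, make_life_table

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def specs():
    return base_case_fixture()


@pytest.fixture(scope="session")
def table():
    return make_life_table()


@pytest.fixture()
def base_draw(specs):
    return specs.base_draw()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)
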
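import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import lepisurvey as lp
from lepisurvey.simulate import DEFAULT_BBOX

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The packaged 30-species Los Angeles 2015 incidence summary."""
    return lp.load_table1_fixture()


@pytest.fixture(scope="session")
def paperlike():
    """Deterministic synthetic world matching the study's marginal structure."""
    return lp.make_paperlike_fixture(seed=1)


@pytest.fixture(scope="session")
def la_filter_config():
    """The study's cleaning settings: 2015 season, LA box, 2500 km cap."""
    return lp.FilterConfig(
        date_start=dt.date(2015, 3, 15),
        date_end=dt.date(2015, 7, 15),
        bbox=DEFAULT_BBOX,
    )
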
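import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from asthmasteps import (
    load_catalogue,
    load_exclusion_rules,
    load_frequency_keywords,
    load_step_rules,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def catalogue_map(catalogue):
    return {e.generic_name: e for e in catalogue}


@pytest.fixture(scope="session")
def exclusion_rules():
    return load_exclusion_rules()


@pytest.fixture(scope="session")
def frequency_keywords():
    return load_frequency_keywords()


@pytest.fixture(scope="session")
def step_rules():
    return load_step_rules()


@pytest.fixture(scope="session")
def study_period():
    return dt.date(2009, 1, 31), dt.date(2017, 3, 31)
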
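import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from theildecomp import (
    load_china_2013_panel,
    load_china_national_totals,
    load_china_regions,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def china_panel():
    return load_china_2013_panel()


@pytest.fixture(scope="session")
def china_regions():
    return load_china_regions()


@pytest.fixture(scope="session")
def china_totals():
    return load_china_national_totals()


@pytest.fixture(scope="session")
def national_totals_2013(china_totals):
    row = china_totals[china_totals["year"] == 2013].iloc[0]
    return {
        "population": float(row["population_10k"]),
        "institutions": float(row["institutions"]),
        "personnel": float(row["personnel"]),
        "beds": float(row["beds"]),
        "investment": float(row["investment_100m_yuan"]),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20130931)
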
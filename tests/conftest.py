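import warnings

import pytest

from countyswing.config import GeneratorConfig
from countyswing.rates import age_adjust, rate_deltas
from countyswing.standards import us2000_standard_million
from countyswing.synthetic import generate_panel

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_data():
    """120 counties in 12 states: fast fixture for unit tests."""
    return generate_panel(GeneratorConfig(seed=11, n_states=12, n_counties_total=120))


@pytest.fixture(scope="session")
def mid_data():
    """600 counties in 30 states: enough structure for model fits."""
    return generate_panel(GeneratorConfig(seed=5, n_states=30, n_counties_total=600))


@pytest.fixture(scope="session")
def mid_rate_deltas(mid_data):
    std = us2000_standard_million()
    allcause = mid_data.deaths[mid_data.deaths["cause_group"] == "all_cause"]
    return rate_deltas(age_adjust(allcause, std))


@pytest.fixture(scope="session")
def mid_design(mid_data, mid_rate_deltas):
    from countyswing.design import build_design

    return build_design(mid_data.panel, mid_rate_deltas)
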
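import pytest

from catpop.simulator import CatastropheSpec, FlowSpec, SimConfig
from catpop.stratification import DEFAULT_SIZE_CLASSES, extrapolate_national
from catpop.synthetic_data import table_baseline_census


@pytest.fixture(scope="session")
def fixture_census():
    """The deterministic synthetic national census (inverse-solved)."""
    return table_baseline_census()


@pytest.fixture(scope="session")
def baseline(fixture_census):
    """National baseline table extrapolated from the fixture census."""
    return extrapolate_national(DEFAULT_SIZE_CLASSES, fixture_census)


@pytest.fixture
def quiet_config():
    """Config with flows and catastrophes off, for closed-form checks."""

    def make(**kwargs):
        defaults = dict(
            catastrophe=CatastropheSpec(annual_probability=0.0),
            flows=FlowSpec(national_abandonment=0, national_adoption=0),
            seed=123,
        )
        defaults.update(kwargs)
        return SimConfig(**defaults)

    return make
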
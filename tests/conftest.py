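import pytest
from hypothesis import HealthCheck, settings

import tsmr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table2():
    """Embedded uridine exposure set and the three AF outcome sets."""
    return tsmr.table2_fixture()


@pytest.fixture(scope="session")
def nielsen_instruments(table2):
    exposure, outcomes = table2
    return tsmr.harmonize(exposure, outcomes["nielsen"])


@pytest.fixture(scope="session")
def nielsen_ratios(nielsen_instruments):
    return tsmr.wald_ratios(nielsen_instruments)


@pytest.fixture(scope="session")
def finngen_ratios(table2):
    exposure, outcomes = table2
    return tsmr.wald_ratios(tsmr.harmonize(exposure, outcomes["finngen"]))
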
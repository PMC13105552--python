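import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crcscreen as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return cs.default_parameters()


@pytest.fixture(scope="session")
def base_grid(params):
    """Base-case 7x6 strategy grid with aged entry cohorts (plus baselines)."""
    return cs.run_strategy_grid(params)


@pytest.fixture(scope="session")
def outcomes_52(base_grid):
    """Outcomes at entry age 52 keyed by frequency, incl. the baseline."""
    return base_grid[52]


def no_death_unit_utility(params):
    """Parameter set with no mortality and utility 1 everywhere (bookkeeping oracle)."""
    p = params
    for band, _ in p.band_items("background_mortality"):
        p = p.with_value("background_mortality", 0.0, age=band.lower)
    for band, _ in p.band_items("utility_general"):
        p = p.with_value("utility_general", 1.0, age=band.lower)
    for stage in range(1, 5):
        p = p.with_value(f"survival5_crc{stage}", 1.0)
        p = p.with_value(f"utility_crc{stage}", 1.0)
    return p.with_value("utility_aa", 1.0)
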
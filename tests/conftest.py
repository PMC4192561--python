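import numpy as np
import pytest

from mobconfound import Unit, simulate_registry
from mobconfound.synthetic import SeasonalModel, default_scenario


@pytest.fixture(scope="session")
def null_registry():
    """1,000 records from a constant-rate generator (no seasonality, no noise)."""
    model = SeasonalModel(
        baseline_annual_births=60_000.0,
        amplitude0=0.0,
        extra_dispersion=0.0,
        latitude_coeff=0.0,
        decline_coeff=1.0,
    )
    units = [Unit(f"N{i:02d}", 50.0, 1_000_000) for i in range(25)]
    return simulate_registry(model, units, range(1961, 2001), seed=11)


@pytest.fixture(scope="session")
def scenario():
    """The default structured study: latitude/time-graded registry,
    north-weighted prevalence, middle-cohort year-of-birth weights."""
    return default_scenario(seed=1)


@pytest.fixture
def toy_record_counts():
    return np.array([120.0, 80.0] + [100.0] * 10)
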
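import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenocap.types import (FLAG_MISSING, FLAG_OBSERVED, ClimateScenario,
                            HourlyTemperatureSeries, SnowSeason)
from phenocap.synthetic import simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("ci")


def make_series(temps, year=2001, start_doy=150, location="loc",
                treatment="ambient", missing=()):
    """Construct an hourly series from a plain list of temperatures."""
    temps = np.asarray(temps, dtype=float)
    start = (pd.Timestamp(year=year, month=1, day=1)
             + pd.Timedelta(days=start_doy - 1))
    index = pd.date_range(start, periods=len(temps), freq="h")
    flags = np.full(len(temps), FLAG_OBSERVED, dtype=object)
    for i in missing:
        temps[i] = np.nan
        flags[i] = FLAG_MISSING
    return HourlyTemperatureSeries(location, treatment, year, index,
                                   temps, flags)


@pytest.fixture(scope="session")
def cold_scenario():
    return ClimateScenario(
        region_label="loc", season_start=150, season_end=200,
        peak_mean_c=6.0, peak_doy=180.0, half_width_days=25.0,
        diurnal_amplitude=3.0, ar1_coefficient=0.7, noise_sd=2.0,
        snowmelt_mean_doy=160.0, snowmelt_sd=3.0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete simulated warming study (4 years, 6 plots)."""
    return simulate_dataset(n_years=4, n_plots=6, seed=11)


@pytest.fixture()
def snow_at(request):
    def _make(doy, location="loc", treatment="ambient", year=2001):
        return SnowSeason(location, treatment, year, doy, "observed")
    return _make
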
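"""Core data containers.

Tabular data moves through the pipeline as pandas DataFrames with documented
column schemas (see :mod:`phenocap.io`); the dataclasses here bundle parameter
sets and per-(location, treatment, year) series with their metadata.

Temperatures are degrees Celsius, time is hourly, forcing is degree-days.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError

TREATMENTS = ("ambient", "warmed")

#: hourly record provenance flags
FLAG_OBSERVED = "observed"
FLAG_INFILLED_1H = "infilled_1h"
FLAG_INFILLED_24H = "infilled_24h"
FLAG_INFILLED_24H_ONE_SIDED = "infilled_24h_one_sided"
FLAG_MISSING = "missing"

TEMP_BOUNDS = (-60.0, 40.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ClimateScenario:
    """Seasonal climate of one tundra region.

    The daily mean temperature follows a Gaussian seasonal curve
    ``peak_mean_c * exp(-0.5 ((doy - peak_doy)/half_width_days)^2)`` evaluated
    once per calendar day, a diurnal sinusoid (amplitude ``diurnal_amplitude``,
    maximum at 15:00) varies within the day, and an AR(1) process with
    marginal standard deviation ``noise_sd`` and lag-1 correlation
    ``ar1_coefficient`` supplies hour-to-hour weather noise.
    """

    region_label: str
    season_start: int  # day of year of the first simulated day
    season_end: int    # day of year of the last simulated day (inclusive)
    peak_mean_c: float
    peak_doy: float
    half_width_days: float
    diurnal_amplitude: float
    ar1_coefficient: float
    noise_sd: float
    snowmelt_mean_doy: float
    snowmelt_sd: float

    def __post_init__(self) -> None:
        _require(self.diurnal_amplitude >= 0, "diurnal_amplitude must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(0 <= self.ar1_coefficient < 1,
                 "ar1_coefficient must be in [0, 1)")
        _require(self.half_width_days > 0, "half_width_days must be > 0")
        _require(self.snowmelt_sd >= 0, "snowmelt_sd must be >= 0")
        _require(self.season_start < self.snowmelt_mean_doy < self.season_end,
                 "season_start < snowmelt_mean_doy < season_end is required")


@dataclass(frozen=True)
class WarmingSpec:
    """Passive (open-top-chamber-like) warming treatment.

    The added temperature follows a solar proxy: a diurnal sinusoid clipped at
    zero during night hours, so daytime maxima rise by up to
    ``peak_daytime_delta`` while night hours rise by exactly
    ``nighttime_delta``.  ``seasonal_decay`` shrinks the daytime component
    linearly from full strength at season start to ``1 - seasonal_decay`` of it
    at season end (warming chambers are most effective under high sun).
    """

    peak_daytime_delta: float = 3.0
    nighttime_delta: float = 0.2
    seasonal_decay: float = 0.5

    def __post_init__(self) -> None:
        _require(self.peak_daytime_delta >= self.nighttime_delta >= 0,
                 "peak_daytime_delta >= nighttime_delta >= 0 is required")
        _require(0 <= self.seasonal_decay <= 1,
                 "seasonal_decay must be in [0, 1]")


@dataclass(frozen=True)
class SpeciesResponse:
    """Generative thermal-time response of one (synthetic) species.

    Each flower bud carries a thermal requirement (degree-days of capped
    forcing) drawn from a lognormal with mean ``mean_thermal_requirement`` and
    coefficient of variation ``requirement_cv``; the bud opens the first hour
    cumulative forcing reaches its requirement.  ``true_tmax`` is the cap used
    when accumulating that forcing; ``None`` gives a linear (uncapped)
    responder.
    """

    name: str
    true_tmax: Optional[float]
    mean_thermal_requirement: float
    requirement_cv: float
    buds_per_plot_mean: float
    senescence_duration: float  # days a flower remains non-senesced

    def __post_init__(self) -> None:
        if self.true_tmax is not None:
            _require(self.true_tmax > 0, "true_tmax must be > 0 when present")
        _require(self.mean_thermal_requirement > 0,
                 "mean_thermal_requirement must be > 0")
        _require(self.requirement_cv > 0, "requirement_cv must be > 0")
        _require(self.buds_per_plot_mean > 0, "buds_per_plot_mean must be > 0")
        _require(self.senescence_duration >= 1,
                 "senescence_duration must be >= 1 day")


@dataclass
class HourlyTemperatureSeries:
    """One season of hourly canopy temperatures for a location x treatment.

    ``index`` is a strictly hourly DatetimeIndex covering the season with no
    holes; genuinely missing hours are present with ``temp_c`` = NaN and
    ``flag`` = "missing".
    """

    location: str
    treatment: str
    year: int
    index: pd.DatetimeIndex
    temp_c: np.ndarray
    flag: np.ndarray

    def __post_init__(self) -> None:
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.flag = np.asarray(self.flag, dtype=object)
        n = len(self.index)
        if len(self.temp_c) != n or len(self.flag) != n:
            raise StructuralError("index, temp_c and flag lengths differ")

    def validate(self) -> None:
        """Check the hourly-grid and physical-range invariants."""
        diffs = np.diff(self.index.asi8)
        if len(diffs) and not np.all(diffs == 3_600_000_000_000):
            raise StructuralError(
                f"{self.location}/{self.treatment}/{self.year}: timestamps "
                "are not on a strict 1-hour grid")
        vals = self.temp_c[~np.isnan(self.temp_c)]
        lo, hi = TEMP_BOUNDS
        if len(vals) and (vals.min() < lo or vals.max() > hi):
            raise StructuralError(
                f"temperatures outside physical bounds [{lo}, {hi}] C")

    @property
    def doy(self) -> np.ndarray:
        """Integer day of year per record."""
        return self.index.dayofyear.to_numpy()

    @property
    def hour(self) -> np.ndarray:
        return self.index.hour.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.flag == FLAG_MISSING))

    def copy(self) -> "HourlyTemperatureSeries":
        return HourlyTemperatureSeries(
            self.location, self.treatment, self.year,
            self.index.copy(), self.temp_c.copy(), self.flag.copy())

    def with_values(self, temp_c: np.ndarray, flag: np.ndarray,
                    treatment: Optional[str] = None) -> "HourlyTemperatureSeries":
        return HourlyTemperatureSeries(
            self.location, treatment or self.treatment, self.year,
            self.index, np.asarray(temp_c, float), np.asarray(flag, object))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "location": self.location,
            "treatment": self.treatment,
            "timestamp": self.index,
            "temp_c": self.temp_c,
            "flag": self.flag.astype(str),
        })


@dataclass(frozen=True)
class SnowSeason:
    """Snowmelt date for one location x treatment x year.

    Days strictly before ``snowmelt_doy`` count as snow-covered; thermal-time
    accumulation is zero there.
    """

    location: str
    treatment: str
    year: int
    snowmelt_doy: int
    source: str = "observed"  # or "simulated"


@dataclass
class ForcingSeries:
    """Cumulative environmental forcing on the hourly grid of one season.

    ``forcing_type`` is one of "DOY", "GDD", "GDD_MAX".  For the GDD types the
    values are cumulative degree-days, zero at and before snowmelt;
    ``tmax_threshold`` is present iff the type is "GDD_MAX".  For "DOY" the
    values are the fractional day of year of each hour (a convenience so every
    forcing is queried through the same interface).
    """

    location: str
    treatment: str
    year: int
    forcing_type: str
    tmax_threshold: Optional[float]
    index: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.index):
            raise StructuralError("forcing values and index lengths differ")
        if self.forcing_type == "GDD_MAX" and self.tmax_threshold is None:
            raise ParameterError("GDD_MAX forcing requires tmax_threshold")
        if self.forcing_type != "GDD_MAX" and self.tmax_threshold is not None:
            raise ParameterError(
                "tmax_threshold only meaningful for GDD_MAX forcing")

    @property
    def total(self) -> float:
        return float(self.values[-1])


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded by the census generator.

    ``openings`` has one row per bud that opened:
    (species, location, treatment, plot, bud_id, open_time, open_doy, year).
    """

    scenario: ClimateScenario
    warming: Optional[WarmingSpec]
    responses: tuple
    seed: int
    openings: pd.DataFrame
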
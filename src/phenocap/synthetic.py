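"""Synthetic tundra climate and flower-census generator.

Emulates the statistical structure the downstream analysis assumes: hourly
canopy temperatures with a seasonal trend, diurnal cycle and AR(1) weather
noise for a colder (high-Arctic) and a warmer (low-Arctic) region; a passive
warming treatment that raises daily maxima much more than daily means and
leaves night-time minima nearly unchanged; snowmelt dates; and plot-level
flower censuses generated from a capped thermal-time response with a known
true temperature cap.  Every stage is a pure function of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError
from .types import (FLAG_OBSERVED, ClimateScenario, ForcingSeries,
                    HourlyTemperatureSeries, SnowSeason, SpeciesResponse,
                    SyntheticTruth, WarmingSpec)

#: Hour of day at which both the diurnal temperature cycle and the warming
#: solar proxy peak (typical canopy-temperature maximum).
DIURNAL_PEAK_HOUR = 15

#: Default scenarios: a colder high-Arctic coastal site and a warmer
#: low-Arctic inland site.  Midsummer daily means near 6 C vs 10 C, with the
#: warmer site also having a larger diurnal range.
HIGH_ARCTIC = ClimateScenario(
    region_label="high_arctic",
    season_start=150, season_end=250,
    peak_mean_c=6.0, peak_doy=200.0, half_width_days=30.0,
    diurnal_amplitude=3.0, ar1_coefficient=0.75, noise_sd=2.5,
    snowmelt_mean_doy=163.0, snowmelt_sd=4.0)

LOW_ARCTIC = ClimateScenario(
    region_label="low_arctic",
    season_start=145, season_end=250,
    peak_mean_c=10.0, peak_doy=198.0, half_width_days=32.0,
    diurnal_amplitude=4.5, ar1_coefficient=0.75, noise_sd=3.0,
    snowmelt_mean_doy=156.0, snowmelt_sd=4.0)

DEFAULT_WARMING = WarmingSpec()

#: Default warmed-minus-ambient snowmelt advance (days).  Field value unknown;
#: chambers melt out slightly earlier, so a small advance is used.
DEFAULT_SNOWMELT_ADVANCE = 2.0

DEFAULT_SPECIES = SpeciesResponse(
    name="synthflora", true_tmax=5.0, mean_thermal_requirement=80.0,
    requirement_cv=0.15, buds_per_plot_mean=8.0, senescence_duration=7.0)


def _season_index(scenario: ClimateScenario, year: int) -> pd.DatetimeIndex:
    start = (pd.Timestamp(year=year, month=1, day=1)
             + pd.Timedelta(days=scenario.season_start - 1))
    n_hours = (scenario.season_end - scenario.season_start + 1) * 24
    return pd.date_range(start, periods=n_hours, freq="h")


def seasonal_mean_curve(scenario: ClimateScenario, doy: np.ndarray) -> np.ndarray:
    """Daily mean temperature at integer day of year (Gaussian seasonal bump)."""
    z = (np.asarray(doy, float) - scenario.peak_doy) / scenario.half_width_days
    return scenario.peak_mean_c * np.exp(-0.5 * z ** 2)


def diurnal_cycle(hour: np.ndarray, amplitude: float) -> np.ndarray:
    """Within-day sinusoid peaking at :data:`DIURNAL_PEAK_HOUR`."""
    return amplitude * np.cos(2 * np.pi * (np.asarray(hour, float)
                                           - DIURNAL_PEAK_HOUR) / 24.0)


def solar_proxy(hour: np.ndarray) -> np.ndarray:
    """Diurnal sinusoid clipped at zero: positive by day, zero at night."""
    return np.clip(np.cos(2 * np.pi * (np.asarray(hour, float)
                                       - DIURNAL_PEAK_HOUR) / 24.0), 0.0, None)


def simulate_hourly_temperatures(scenario: ClimateScenario, year: int,
                                 seed) -> HourlyTemperatureSeries:
    """Simulate one season of hourly ambient canopy temperatures.

    temperature = seasonal daily mean + diurnal sinusoid + AR(1) noise.
    The seasonal mean curve is evaluated per calendar day (constant within a
    day) so the diurnal sinusoid is the only deterministic within-day term.
    The AR(1) noise has marginal standard deviation ``noise_sd`` and lag-1
    autocorrelation ``ar1_coefficient``.  All records are flagged "observed".
    """
    rng = np.random.default_rng(seed)
    index = _season_index(scenario, year)
    doy = index.dayofyear.to_numpy()
    hour = index.hour.to_numpy()
    base = seasonal_mean_curve(scenario, doy) + diurnal_cycle(
        hour, scenario.diurnal_amplitude)

    n = len(index)
    noise = np.zeros(n)
    if scenario.noise_sd > 0:
        phi = scenario.ar1_coefficient
        innov_sd = scenario.noise_sd * np.sqrt(1.0 - phi ** 2)
        eps = rng.normal(0.0, 1.0, size=n)
        noise[0] = scenario.noise_sd * eps[0]
        for t in range(1, n):
            noise[t] = phi * noise[t - 1] + innov_sd * eps[t]

    flags = np.full(n, FLAG_OBSERVED, dtype=object)
    series = HourlyTemperatureSeries(scenario.region_label, "ambient", year,
                                     index, base + noise, flags)
    series.validate()
    return series


def apply_warming(series: HourlyTemperatureSeries,
                  spec: WarmingSpec) -> HourlyTemperatureSeries:
    """Apply the passive-warming delta to an ambient hourly series.

    delta(t) = nighttime_delta
               + (peak_daytime_delta - nighttime_delta) * solar_proxy(hour)
                 * (1 - seasonal_decay * season_fraction)

    Night hours (solar proxy zero) are warmed by exactly ``nighttime_delta``;
    the daytime component decays linearly across the season.  The returned
    series is labelled treatment "warmed".
    """
    doy = series.doy.astype(float)
    span = max(float(doy[-1] - doy[0]), 1.0)
    frac = (doy - doy[0]) / span
    decay = 1.0 - spec.seasonal_decay * frac
    delta = (spec.nighttime_delta
             + (spec.peak_daytime_delta - spec.nighttime_delta)
             * solar_proxy(series.hour) * decay)
    return series.with_values(series.temp_c + delta, series.flag.copy(),
                              treatment="warmed")


def simulate_snowmelt(scenario: ClimateScenario, warming_advance_days: float,
                      seed) -> Dict[str, int]:
    """Draw a snowmelt day of year for each treatment for one year.

    Ambient melt ~ Normal(snowmelt_mean_doy, snowmelt_sd), rounded to a day;
    warmed melt is ``warming_advance_days`` earlier, floored at season start.
    """
    if warming_advance_days < 0:
        raise ParameterError("warming_advance_days must be >= 0")
    rng = np.random.default_rng(seed)
    ambient = int(round(rng.normal(scenario.snowmelt_mean_doy,
                                   scenario.snowmelt_sd)))
    ambient = int(np.clip(ambient, scenario.season_start, scenario.season_end))
    warmed = int(max(scenario.season_start,
                     round(ambient - warming_advance_days)))
    return {"ambient": ambient, "warmed": warmed}


def _census_dates(forcing: ForcingSeries, census_interval: float,
                  jitter_days: float, rng) -> pd.DatetimeIndex:
    """Regular census schedule from just before forcing onset to season end."""
    onset = np.argmax(forcing.values > 0) if forcing.values[-1] > 0 else 0
    first = forcing.index[onset].normalize() - pd.Timedelta(days=census_interval)
    # never schedule so early that the first census midpoint (half an
    # interval before the census) falls outside the covered season
    earliest = forcing.index[0].normalize() + pd.Timedelta(days=census_interval)
    first = max(first, earliest)
    dates = []
    t = first
    end = forcing.index[-1]
    while t <= end:
        d = t
        if jitter_days > 0 and dates:  # keep the anchor census fixed
            d = t + pd.Timedelta(days=float(rng.integers(
                -int(jitter_days), int(jitter_days) + 1)))
            d = min(max(d, forcing.index[0].normalize()), end.normalize())
        dates.append(d)
        t = t + pd.Timedelta(days=census_interval)
    # a closing census on the last covered day, so late openers are seen
    if dates and dates[-1] < end.normalize():
        dates.append(end.normalize())
    return pd.DatetimeIndex(sorted(set(dates)))


def simulate_censuses(forcing: ForcingSeries, response: SpeciesResponse,
                      n_plots: int, census_interval: float, seed,
                      jitter_days: float = 0.0,
                      record_senesced: bool = True,
                      plot_prefix: str = "P") -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate plot-level flower censuses from a thermal-time response.

    Per plot the bud count is Poisson(``buds_per_plot_mean``); each bud's
    thermal requirement is lognormal with mean ``mean_thermal_requirement``
    and CV ``requirement_cv``.  A bud opens at the first hour cumulative
    forcing reaches its requirement (buds whose requirement is never reached
    do not open).  At a census (taken at 12:00) a flower is counted
    non-senesced if it opened within ``senescence_duration`` days before the
    census time, senesced thereafter.

    ``forcing`` must be the accumulation produced with the generator's own
    ``true_tmax`` (or the uncapped accumulation for a linear responder).
    With ``record_senesced=False`` the protocol scores open flowers only
    (n_senesced stays 0), emulating surveys where wilted flowers are not
    tallied; then each flower enters the new-flower derivation exactly once
    provided it is open at exactly one census.

    Returns ``(censuses, openings)``: the census table
    (species, plot, location, treatment, date, n_open, n_senesced) and the
    ground-truth opening table.
    """
    if n_plots < 1:
        raise ParameterError("n_plots must be >= 1")
    rng = np.random.default_rng(seed)
    dates = _census_dates(forcing, census_interval, jitter_days, rng)
    if len(dates) == 0:
        raise CoverageError("forcing series does not cover any census dates")
    census_ts = dates + pd.Timedelta(hours=12)

    # lognormal parameterized by mean m and CV c:
    # sigma^2 = ln(1 + c^2), mu = ln m - sigma^2 / 2
    sigma2 = np.log1p(response.requirement_cv ** 2)
    mu = np.log(response.mean_thermal_requirement) - sigma2 / 2.0

    cum = forcing.values
    t_ns = forcing.index.asi8
    census_ns = census_ts.asi8
    senes_ns = int(response.senescence_duration * 24 * 3600 * 1e9)

    census_rows = []
    truth_rows = []
    for p in range(n_plots):
        plot = f"{plot_prefix}{p + 1:02d}"
        n_buds = rng.poisson(response.buds_per_plot_mean)
        reqs = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n_buds))
        idx = np.searchsorted(cum, reqs, side="left")
        opened = idx < len(cum)
        open_ns = t_ns[idx[opened]]
        for b, ons in zip(np.nonzero(opened)[0], open_ns):
            ts = pd.Timestamp(ons)
            truth_rows.append((response.name, forcing.location,
                               forcing.treatment, plot, f"{plot}-b{b + 1}",
                               ts, ts.dayofyear + ts.hour / 24.0,
                               forcing.year))
        for d, cns in zip(dates, census_ns):
            age = cns - open_ns
            n_open = int(np.sum((age >= 0) & (age < senes_ns)))
            n_sen = int(np.sum(age >= senes_ns)) if record_senesced else 0
            census_rows.append((response.name, plot, forcing.location,
                                forcing.treatment, d, n_open, n_sen))

    censuses = pd.DataFrame(census_rows, columns=[
        "species", "plot", "location", "treatment", "date",
        "n_open", "n_senesced"])
    openings = pd.DataFrame(truth_rows, columns=[
        "species", "location", "treatment", "plot", "bud_id",
        "open_time", "open_doy", "year"])
    return censuses, openings


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, keyed by (treatment, year)."""

    scenario: ClimateScenario
    warming: WarmingSpec
    response: SpeciesResponse
    seed: int
    years: tuple
    temps: Dict[Tuple[str, int], HourlyTemperatureSeries]
    snow: Dict[Tuple[str, int], SnowSeason]
    censuses: pd.DataFrame
    first_flower: pd.DataFrame
    truth: SyntheticTruth

    def ambient_temps(self) -> Dict[int, HourlyTemperatureSeries]:
        return {y: self.temps[("ambient", y)] for y in self.years}

    def ambient_snow(self) -> Dict[int, SnowSeason]:
        return {y: self.snow[("ambient", y)] for y in self.years}


def simulate_dataset(scenario: ClimateScenario = HIGH_ARCTIC,
                     warming: WarmingSpec = DEFAULT_WARMING,
                     response: SpeciesResponse = DEFAULT_SPECIES,
                     n_years: int = 10,
                     first_year: int = 2001,
                     n_plots: int = 24,
                     census_interval: float = 7.0,
                     snowmelt_advance_days: float = DEFAULT_SNOWMELT_ADVANCE,
                     jitter_days: float = 0.0,
                     seed: int = 0) -> SyntheticDataset:
    """Simulate a complete multi-year warming study for one species.

    For every year: ambient temperatures, the warmed series derived from
    them, per-treatment snowmelt, the true (possibly capped) forcing, and
    independent plot-level censuses for 24 ambient and 24 warmed plots.
    Deterministic given (parameters, seed).
    """
    from .thermal_time import accumulate  # local import to avoid a cycle

    root = np.random.SeedSequence(seed)
    years = tuple(range(first_year, first_year + n_years))
    streams = root.spawn(n_years)

    temps: Dict[Tuple[str, int], HourlyTemperatureSeries] = {}
    snow: Dict[Tuple[str, int], SnowSeason] = {}
    census_parts = []
    truth_parts = []
    for year, stream in zip(years, streams):
        s_temp, s_snow, s_amb, s_wrm = stream.spawn(4)
        ambient = simulate_hourly_temperatures(scenario, year, s_temp)
        warmed = apply_warming(ambient, warming)
        melt = simulate_snowmelt(scenario, snowmelt_advance_days, s_snow)
        temps[("ambient", year)] = ambient
        temps[("warmed", year)] = warmed
        for trt, series, cseed, prefix in (
                ("ambient", ambient, s_amb, "A"),
                ("warmed", warmed, s_wrm, "W")):
            snow[(trt, year)] = SnowSeason(scenario.region_label, trt, year,
                                           melt[trt], source="simulated")
            forcing = accumulate(series, snow[(trt, year)], response.true_tmax)
            cen, opened = simulate_censuses(
                forcing, response, n_plots, census_interval, cseed,
                jitter_days=jitter_days, plot_prefix=prefix)
            census_parts.append(cen)
            truth_parts.append(opened)

    censuses = pd.concat(census_parts, ignore_index=True)
    openings = (pd.concat(truth_parts, ignore_index=True)
                if truth_parts else pd.DataFrame())
    truth = SyntheticTruth(scenario, warming, (response,), seed, openings)

    # early-season first-flowering survey: first opening per plot x year
    if len(openings):
        ff = (openings.groupby(
                ["species", "location", "treatment", "plot", "year"],
                as_index=False)["open_time"].min()
              .rename(columns={"open_time": "first_flower_date"}))
        ff["first_flower_date"] = ff["first_flower_date"].dt.normalize()
    else:
        ff = pd.DataFrame(columns=["species", "location", "treatment",
                                   "plot", "year", "first_flower_date"])

    return SyntheticDataset(scenario, warming, response, seed, years,
                            temps, snow, censuses, ff, truth)
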
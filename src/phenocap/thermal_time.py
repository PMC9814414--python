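"""Thermal-time (growing degree day) accumulation.

Three forcing currencies are supported, all on the hourly grid of the input
temperature series:

* ``DOY`` — fractional day of year (the calendar-time null model);
* ``GDD`` — growing degree days: an hour at mean temperature ``T`` snow-free
  contributes ``max(T, 0) / 24`` degree-days, hours before snowmelt
  contribute nothing;
* ``GDD_MAX`` — the same with hourly temperatures capped at a maximum
  threshold ``T_max``, so heat above the cap adds no extra forcing.

Hourly contributions are divided by 24 so cumulative forcing is in
degree-days regardless of resolution; thresholds stay on the familiar scale
and any constant rescaling is absorbed downstream by the spline.
"""
from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DataQualityError, ParameterError
from .types import FLAG_MISSING, ForcingSeries, HourlyTemperatureSeries, SnowSeason


def accumulate(series: HourlyTemperatureSeries, snow: SnowSeason,
               tmax_threshold: Optional[float] = None) -> ForcingSeries:
    """Accumulate (capped) growing degree days over one season.

    Hourly contribution: 0 if the date precedes ``snow.snowmelt_doy`` or the
    temperature is <= 0 C; otherwise ``min(T, tmax_threshold) / 24``
    degree-days (no cap when the threshold is None).  The cumulative sum is
    reported at every hour.

    Raises :class:`DataQualityError` if the series still contains missing
    hours (run :func:`phenocap.temperatures.infill_gaps` first).
    """
    missing = np.isnan(series.temp_c) | (series.flag == FLAG_MISSING)
    if missing.any():
        bad = series.index[missing]
        raise DataQualityError(
            f"{missing.sum()} unfilled missing hours, first at {bad[0]}")
    doy = series.doy
    if not (doy[0] <= snow.snowmelt_doy <= doy[-1]):
        raise CoverageError(
            f"snowmelt_doy {snow.snowmelt_doy} outside series span "
            f"[{doy[0]}, {doy[-1]}]")

    temp = series.temp_c
    contrib = np.where(temp <= 0.0, 0.0, temp)
    if tmax_threshold is not None:
        if tmax_threshold < 0:
            raise ParameterError("tmax_threshold must be >= 0")
        contrib = np.minimum(contrib, tmax_threshold)
        contrib[temp <= 0.0] = 0.0
    contrib = np.where(doy < snow.snowmelt_doy, 0.0, contrib) / 24.0

    ftype = "GDD" if tmax_threshold is None else "GDD_MAX"
    return ForcingSeries(series.location, series.treatment, series.year,
                         ftype, tmax_threshold, series.index,
                         np.cumsum(contrib))


def doy_forcing(series: HourlyTemperatureSeries) -> ForcingSeries:
    """Calendar-time 'forcing': fractional day of year at each hour."""
    vals = series.doy.astype(float) + series.hour / 24.0
    return ForcingSeries(series.location, series.treatment, series.year,
                         "DOY", None, series.index, vals)


def forcing_at(forcing: ForcingSeries, timestamp) -> float:
    """Cumulative forcing accumulated strictly before ``timestamp``.

    Hour records are hour-beginning: the record at 13:00 covers 13:00-14:00
    and is included once the query time passes 13:00.  A query at the series'
    first record (or at snowmelt midnight for GDD types) therefore reads 0;
    a query at the end of the covered span reads the seasonal total.  For
    "DOY" forcing the value is the fractional day of year instead.
    """
    ts = pd.Timestamp(timestamp)
    idx = forcing.index
    if ts < idx[0] or ts > idx[-1] + pd.Timedelta(hours=1):
        raise CoverageError(
            f"timestamp {ts} outside forcing span [{idx[0]}, {idx[-1]}]")
    if forcing.forcing_type == "DOY":
        return float(ts.dayofyear + (ts - ts.normalize()).total_seconds()
                     / 86400.0)
    pos = int(np.searchsorted(idx.asi8, ts.value, side="left")) - 1
    return float(forcing.values[pos]) if pos >= 0 else 0.0


def forcing_at_many(forcing: ForcingSeries, timestamps) -> np.ndarray:
    """Vectorized :func:`forcing_at` for an iterable of timestamps."""
    ts = pd.DatetimeIndex(timestamps)
    idx = forcing.index
    if len(ts) and (ts.min() < idx[0] or ts.max() > idx[-1] + pd.Timedelta(hours=1)):
        raise CoverageError("one or more timestamps outside forcing span")
    if forcing.forcing_type == "DOY":
        frac = (ts.asi8 - ts.normalize().asi8) / 86_400e9
        return ts.dayofyear.to_numpy() + frac
    pos = np.searchsorted(idx.asi8, ts.asi8, side="left") - 1
    vals = np.where(pos >= 0, forcing.values[np.clip(pos, 0, None)], 0.0)
    return vals


def forcing_family(series: HourlyTemperatureSeries, snow: SnowSeason,
                   thresholds: Sequence[float]) -> List[ForcingSeries]:
    """One capped forcing per threshold plus the uncapped series, sharing
    timestamps.  ``thresholds`` must be sorted ascending."""
    thr = list(thresholds)
    if any(b < a for a, b in zip(thr, thr[1:])):
        raise ParameterError("thresholds must be sorted ascending")
    out = [accumulate(series, snow, t) for t in thr]
    out.append(accumulate(series, snow, None))
    return out
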
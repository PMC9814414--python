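"""Hourly temperature validation, gap infilling and daily diagnostics.

Gap infilling follows the field protocol for canopy temperature loggers:
an isolated one-hour gap is filled with the mean of the previous and
following hours; longer gaps are filled hour-by-hour with the mean of the
temperatures 24 h earlier and 24 h later.  Rules are re-applied until no
further hour can be filled, which makes the operation idempotent; hours whose
+/- 24 h references are both unavailable stay missing and are reported.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DataQualityError, ParameterError
from .types import (FLAG_INFILLED_1H, FLAG_INFILLED_24H,
                    FLAG_INFILLED_24H_ONE_SIDED, FLAG_MISSING, FLAG_OBSERVED,
                    HourlyTemperatureSeries)

logger = logging.getLogger(__name__)


def infill_gaps(series: HourlyTemperatureSeries) -> HourlyTemperatureSeries:
    """Fill missing hours by the one-hour and 24-hour rules.

    A gap is "one hour" iff both adjacent hours are non-missing: it gets the
    mean of its neighbours (flag ``infilled_1h``).  Hours in longer runs get
    the mean of the values 24 h before and 24 h after; if only one reference
    exists that value is used alone, with the distinct flag
    ``infilled_24h_one_sided``.  Sweeps repeat until a fixed point, so
    applying the function twice changes nothing.  Observed values and flags
    are never altered.
    """
    temp = series.temp_c.copy()
    flag = series.flag.copy()
    n = len(temp)
    miss = np.isnan(temp) | (flag == FLAG_MISSING)
    temp[miss] = np.nan
    flag[miss] = FLAG_MISSING
    if n and miss.all():
        raise DataQualityError("series has no non-missing records")

    changed = True
    while changed:
        changed = False
        miss = np.isnan(temp)
        if not miss.any():
            break
        # classify runs of consecutive missing hours on the current mask
        starts = np.nonzero(miss & ~np.roll(miss, 1))[0]
        if miss[0]:
            starts = np.union1d(starts, [0])
        for s in starts:
            e = s
            while e + 1 < n and miss[e + 1]:
                e += 1
            run = range(s, e + 1)
            one_hour = (len(run) == 1 and s - 1 >= 0 and e + 1 < n
                        and not np.isnan(temp[s - 1])
                        and not np.isnan(temp[e + 1]))
            if one_hour:
                temp[s] = 0.5 * (temp[s - 1] + temp[s + 1])
                flag[s] = FLAG_INFILLED_1H
                changed = True
                continue
            for i in run:
                refs = [temp[j] for j in (i - 24, i + 24)
                        if 0 <= j < n and not np.isnan(temp[j])]
                if len(refs) == 2:
                    temp[i] = 0.5 * (refs[0] + refs[1])
                    flag[i] = FLAG_INFILLED_24H
                    changed = True
                elif len(refs) == 1:
                    temp[i] = refs[0]
                    flag[i] = FLAG_INFILLED_24H_ONE_SIDED
                    changed = True

    remaining = int(np.isnan(temp).sum())
    if remaining:
        logger.warning("%s/%s/%s: %d hours unfillable (both 24 h references "
                       "missing)", series.location, series.treatment,
                       series.year, remaining)
    return series.with_values(temp, flag)


INFILLED_FLAGS = (FLAG_INFILLED_1H, FLAG_INFILLED_24H,
                  FLAG_INFILLED_24H_ONE_SIDED)


def daily_summaries(series: HourlyTemperatureSeries,
                    min_hours: int = 20) -> pd.DataFrame:
    """Per-calendar-day min/mean/max with provenance counts.

    Returns a DataFrame (date, t_min, t_mean, t_max, n_hours_observed,
    n_hours_infilled, complete) where ``complete`` marks days with at least
    ``min_hours`` available (non-missing) hours.
    """
    df = pd.DataFrame({"date": series.index.normalize(),
                       "temp": series.temp_c,
                       "flag": series.flag.astype(str)})
    avail = df.dropna(subset=["temp"])
    g = avail.groupby("date")["temp"]
    out = pd.DataFrame({"t_min": g.min(), "t_mean": g.mean(), "t_max": g.max()})
    out["n_hours_observed"] = (avail[avail["flag"] == FLAG_OBSERVED]
                               .groupby("date").size())
    out["n_hours_infilled"] = (avail[avail["flag"].isin(INFILLED_FLAGS)]
                               .groupby("date").size())
    out = out.fillna({"n_hours_observed": 0, "n_hours_infilled": 0})
    out[["n_hours_observed", "n_hours_infilled"]] = out[
        ["n_hours_observed", "n_hours_infilled"]].astype(int)
    out["complete"] = (out["n_hours_observed"] + out["n_hours_infilled"]
                       >= min_hours)
    return out.reset_index()


def warming_effect(ambient: pd.DataFrame, warmed: pd.DataFrame,
                   window: int = 7) -> pd.DataFrame:
    """Daily warmed-minus-ambient differences with centred rolling means.

    Differences are computed on common dates only.  The rolling mean uses a
    centred ``window``-day window, shrinking to the available part at the
    series edges.
    """
    a = ambient.set_index("date")
    w = warmed.set_index("date")
    common = a.index.intersection(w.index)
    if len(common) == 0:
        raise CoverageError("ambient and warmed summaries share no dates")
    out = pd.DataFrame(index=common.sort_values())
    for stat in ("min", "mean", "max"):
        col = f"t_{stat}"
        out[f"d_{stat}"] = w.loc[out.index, col] - a.loc[out.index, col]
        out[f"roll_{stat}"] = (out[f"d_{stat}"]
                               .rolling(window, center=True, min_periods=1)
                               .mean())
    return out.reset_index().rename(columns={"index": "date"})


def summer_temperature_quantile(series, q: float, snow,
                                months: Sequence[int] = (6, 7, 8)) -> float:
    """Empirical quantile of snow-free summer hourly temperatures.

    ``series``/``snow`` may be single objects or aligned lists (years pooled).
    Hours count as summer when the month is in ``months`` and the date is on
    or after the snowmelt date of the matching year.  Quantile convention:
    linear interpolation between order statistics (type 7, the numpy default).
    """
    if not 0 < q < 1:
        raise ParameterError("q must be in (0, 1)")
    if isinstance(series, HourlyTemperatureSeries):
        series, snow = [series], [snow]
    vals = []
    for s, sn in zip(series, snow):
        mask = (np.isin(s.index.month, list(months))
                & (s.doy >= sn.snowmelt_doy)
                & ~np.isnan(s.temp_c))
        vals.append(s.temp_c[mask])
    pooled = np.concatenate(vals) if vals else np.array([])
    if pooled.size == 0:
        raise CoverageError("no snow-free summer hours in the restriction")
    return float(np.quantile(pooled, q))
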
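"""CSV dialects shared by the pipeline stages and the CLI.

All artifacts are plain CSV with ISO-8601 timestamps:

* temperatures: location, treatment, timestamp, temp_c, flag
* snowmelt:     location, treatment, year, melt_doy
* censuses:     species, plot, location, treatment, date, n_open, n_senesced
* first flowering: species, plot, location, treatment, year, first_flower_date
* truth:        species, plot, bud_id, open_date (+ location, treatment, year)
* forcing:      location, treatment, year, forcing_type, tmax_threshold,
                timestamp, cumulative_value
* new flowers:  species, location, treatment, year, date, new_flowers,
                interval_days, midpoint, anchored
"""
from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .errors import StructuralError
from .types import ForcingSeries, HourlyTemperatureSeries, SnowSeason

TempKey = Tuple[str, str, int]  # (location, treatment, year)


def write_temperatures(series: Iterable[HourlyTemperatureSeries],
                       path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False)


def read_temperatures(path) -> Dict[TempKey, HourlyTemperatureSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out: Dict[TempKey, HourlyTemperatureSeries] = {}
    for (loc, trt), grp in df.groupby(["location", "treatment"], sort=True):
        for year, sub in grp.groupby(grp["timestamp"].dt.year):
            sub = sub.sort_values("timestamp")
            s = HourlyTemperatureSeries(
                loc, trt, int(year), pd.DatetimeIndex(sub["timestamp"]),
                sub["temp_c"].to_numpy(float),
                sub["flag"].to_numpy(object))
            s.validate()
            out[(loc, trt, int(year))] = s
    if not out:
        raise StructuralError(f"no temperature records in {path}")
    return out


def write_snowmelt(seasons: Iterable[SnowSeason], path) -> None:
    pd.DataFrame([{"location": s.location, "treatment": s.treatment,
                   "year": s.year, "melt_doy": s.snowmelt_doy,
                   "source": s.source} for s in seasons]).to_csv(
        path, index=False)


def read_snowmelt(path) -> Dict[TempKey, SnowSeason]:
    df = pd.read_csv(path)
    return {(r.location, r.treatment, int(r.year)):
            SnowSeason(r.location, r.treatment, int(r.year),
                       int(r.melt_doy),
                       getattr(r, "source", "observed"))
            for r in df.itertuples()}


def write_censuses(censuses: pd.DataFrame, path) -> None:
    censuses.to_csv(path, index=False)


def read_censuses(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    need = {"species", "plot", "location", "treatment", "date",
            "n_open", "n_senesced"}
    if not need.issubset(df.columns):
        raise StructuralError(f"census CSV missing columns "
                              f"{sorted(need - set(df.columns))}")
    return df


def write_truth(openings: pd.DataFrame, path) -> None:
    out = openings.copy()
    if "open_time" in out.columns:
        out["open_date"] = pd.to_datetime(out["open_time"]).dt.normalize()
    out.to_csv(path, index=False)


def read_first_flower(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["first_flower_date"])


def write_first_flower(ff: pd.DataFrame, path) -> None:
    ff.to_csv(path, index=False)


def write_forcing(series: Iterable[ForcingSeries], path) -> None:
    parts = []
    for f in series:
        parts.append(pd.DataFrame({
            "location": f.location, "treatment": f.treatment,
            "year": f.year, "forcing_type": f.forcing_type,
            "tmax_threshold": (np.nan if f.tmax_threshold is None
                               else f.tmax_threshold),
            "timestamp": f.index, "cumulative_value": f.values}))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_new_flowers(flowers: pd.DataFrame, path) -> None:
    flowers.to_csv(path, index=False)


def read_new_flowers(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date", "midpoint"])
    if "year" not in df.columns:
        df["year"] = df["date"].dt.year
    return df
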
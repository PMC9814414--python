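"""From plot-level flower censuses to seasonal new-flower count series.

A census records, per plot and species, the number of non-senesced flowers
present and the number of senesced flowers present.  New flowers opened since
the previous census are derived as

    new_t = n_open_t + (n_senesced_t - n_senesced_{t-1})

with the senesced lag taken as 0 at the first census.  Plot series are summed
per treatment x location, a synthetic zero census is prepended when the first
real census already has flowers (two days before the earliest first-flowering
date, since early-season surveys run roughly every other day), and each census
is assigned an intercensus interval and a midpoint date at which forcing is
later evaluated.
"""
from __future__ import annotations

import logging
from typing import Optional, Set, Tuple

import numpy as np
import pandas as pd

from .errors import StructuralError

logger = logging.getLogger(__name__)

GROUP_KEYS = ["species", "location", "treatment"]


def _year(dates: pd.Series) -> pd.Series:
    return pd.to_datetime(dates).dt.year


def derive_new_flowers(obs: pd.DataFrame) -> pd.DataFrame:
    """Derive per-census new-flower counts for a single plot season.

    ``obs`` must be sorted by date and contain columns date, n_open,
    n_senesced.  Returns a copy with ``new_flowers_raw`` (the derivation
    before clamping) and ``new_flowers`` (negatives, which can arise from
    observer error, clamped to zero with a logged warning).
    """
    dates = pd.to_datetime(obs["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise StructuralError("census dates must be strictly increasing")
    out = obs.copy()
    sen = obs["n_senesced"].to_numpy()
    raw = obs["n_open"].to_numpy() + np.diff(sen, prepend=0)
    out["new_flowers_raw"] = raw
    clamped = np.maximum(raw, 0)
    n_neg = int(np.sum(raw < 0))
    if n_neg:
        logger.warning("%d negative new-flower derivations clamped to 0",
                       n_neg)
    out["new_flowers"] = clamped
    return out


def derive_all(censuses: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`derive_new_flowers` per species x plot x season."""
    df = censuses.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    parts = []
    for _, grp in df.groupby(GROUP_KEYS + ["plot", "year"], sort=True):
        parts.append(derive_new_flowers(grp.sort_values("date")))
    return pd.concat(parts, ignore_index=True)


def aggregate_plots(per_plot: pd.DataFrame) -> pd.DataFrame:
    """Sum per-plot new-flower counts over plots.

    All plots within a species x location x treatment x year must share the
    same census schedule.  Returns one row per census date with columns
    new_flowers (plot sum), n_plots and ``anchored`` = False.
    """
    df = per_plot.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    out_parts = []
    for key, grp in df.groupby(GROUP_KEYS + ["year"], sort=True):
        sched = grp.groupby("plot")["date"].apply(
            lambda s: tuple(sorted(s)))
        if sched.nunique() > 1:
            raise StructuralError(
                f"plots disagree on census schedule for {key}")
        agg = (grp.groupby("date", as_index=False)
               .agg(new_flowers=("new_flowers", "sum")))
        for col, val in zip(GROUP_KEYS + ["year"], key):
            agg[col] = val
        agg["n_plots"] = grp["plot"].nunique()
        out_parts.append(agg)
    out = pd.concat(out_parts, ignore_index=True)
    out["anchored"] = False
    return out.sort_values(GROUP_KEYS + ["date"]).reset_index(drop=True)


def anchor_first_census(series: pd.DataFrame,
                        first_flower: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Prepend a synthetic zero census where the season starts mid-bloom.

    For every species x location x treatment x year whose first census
    already has > 0 flowers, a zero-count census is inserted two days before
    the earliest first-flowering date recorded for that combination.  The
    inserted row carries ``anchored`` = True.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    parts = []
    for key, grp in df.groupby(GROUP_KEYS + ["year"], sort=True):
        grp = grp.sort_values("date")
        if grp.iloc[0]["new_flowers"] > 0:
            if first_flower is None or first_flower.empty:
                raise StructuralError(
                    f"first census non-zero for {key} but no first-flowering "
                    "dates supplied")
            ff = first_flower.copy()
            ff["first_flower_date"] = pd.to_datetime(ff["first_flower_date"])
            m = np.ones(len(ff), dtype=bool)
            for col, val in zip(GROUP_KEYS, key[:3]):
                m &= ff[col].to_numpy() == val
            m &= ff["first_flower_date"].dt.year.to_numpy() == key[3]
            if not m.any():
                raise StructuralError(
                    f"no first-flowering date available for {key}")
            anchor_date = ff.loc[m, "first_flower_date"].min() - pd.Timedelta(
                days=2)
            if anchor_date >= grp.iloc[0]["date"]:
                raise StructuralError(
                    f"anchor date {anchor_date.date()} not before first "
                    f"census {grp.iloc[0]['date'].date()} for {key}")
            row = grp.iloc[0].copy()
            row["date"] = anchor_date
            row["new_flowers"] = 0
            row["anchored"] = True
            grp = pd.concat([row.to_frame().T, grp], ignore_index=True)
            grp["new_flowers"] = grp["new_flowers"].astype(int)
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def assign_midpoints(series: pd.DataFrame,
                     default_first_interval: float = 7.0) -> pd.DataFrame:
    """Attach intercensus intervals and midpoint dates.

    interval_t = date_t - date_{t-1} in days for t >= 2 and
    ``default_first_interval`` for the first census of a season;
    midpoint_t = date_t - interval_t / 2 (kept at half-day resolution).
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    parts = []
    for key, grp in df.groupby(GROUP_KEYS + ["year"], sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if grp["date"].duplicated().any():
            raise StructuralError(f"duplicate census dates for {key}")
        days = grp["date"].diff().dt.total_seconds() / 86400.0
        days.iloc[0] = default_first_interval
        grp["interval_days"] = days
        grp["midpoint"] = grp["date"] - pd.to_timedelta(days / 2.0, unit="D")
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def screen_inclusion(series: pd.DataFrame, min_years: int = 10,
                     total_years: int = 13,
                     min_seasonal_total: int = 5
                     ) -> Tuple[Set[Tuple[str, str]], pd.DataFrame]:
    """Select species x locations whose ambient seasons have determinable peaks.

    A season has a determinable peak iff the maximum count occurs at neither
    the first nor the last census and the seasonal total is at least
    ``min_seasonal_total``.  A species x location is included iff at least
    ``min_years`` ambient seasons (out of ``total_years`` surveyed) qualify.
    Returns the included set and an exclusion log.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "year" not in df.columns:
        df["year"] = df["date"].dt.year
    rows = []
    for (sp, loc, trt, yr), grp in df.groupby(
            ["species", "location", "treatment", "year"], sort=True):
        counts = grp.sort_values("date")["new_flowers"].to_numpy()
        total = int(counts.sum())
        peak_ok = False
        if len(counts) >= 3 and total > 0:
            at_max = np.nonzero(counts == counts.max())[0]
            peak_ok = 0 not in at_max and (len(counts) - 1) not in at_max
        rows.append((sp, loc, trt, yr, total,
                     peak_ok and total >= min_seasonal_total))
    qual = pd.DataFrame(rows, columns=["species", "location", "treatment",
                                       "year", "total", "determinable"])
    included: Set[Tuple[str, str]] = set()
    excl_rows = []
    amb = qual[qual["treatment"] == "ambient"]
    for (sp, loc), grp in amb.groupby(["species", "location"]):
        n_good = int(grp["determinable"].sum())
        if n_good >= min_years:
            included.add((sp, loc))
        else:
            excl_rows.append((sp, loc, n_good, min_years,
                              f"only {n_good}/{total_years} ambient years "
                              "with a determinable peak"))
    exclusions = pd.DataFrame(excl_rows, columns=[
        "species", "location", "qualifying_years", "min_years", "reason"])
    for _, r in exclusions.iterrows():
        logger.info("excluded %s at %s: %s", r["species"], r["location"],
                    r["reason"])
    return included, exclusions


def prepare_new_flower_series(censuses: pd.DataFrame,
                              first_flower: Optional[pd.DataFrame] = None,
                              default_first_interval: float = 7.0
                              ) -> pd.DataFrame:
    """Full census-processing chain: derive, aggregate, anchor, midpoints."""
    per_plot = derive_all(censuses)
    agg = aggregate_plots(per_plot)
    anchored = anchor_first_census(agg, first_flower)
    return assign_midpoints(anchored, default_first_interval)
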
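"""Predictive comparison of DOY, GDD and calibrated GDD_max models.

Models are trained on ambient-plot data only, then used (fixed effects only)
to predict the seasonal distribution of flowering in both ambient and
experimentally warmed plots.  Because absolute flower numbers vary strongly
among years and treatments, both predictions and observations are normalized
within each year to percentages of the seasonal total before computing the
root-mean-squared error over censuses, so RMSE is in percentage points and
measures timing, not abundance.
"""
from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import gam
from .errors import DegenerateDataError, ParameterError
from .thermal_time import accumulate, doy_forcing, forcing_at_many
from .types import ForcingSeries, HourlyTemperatureSeries, SnowSeason

logger = logging.getLogger(__name__)

MODEL_TYPES = ("DOY", "GDD", "GDD_MAX")


def normalize_seasonal(counts) -> np.ndarray:
    """Convert within-season counts to percentages summing to 100."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise DegenerateDataError("seasonal total is zero; cannot normalize")
    return arr / total * 100.0


def rmse(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _forcing_for(model_type: str, series: HourlyTemperatureSeries,
                 snow: SnowSeason, threshold: Optional[float]) -> ForcingSeries:
    if model_type == "DOY":
        return doy_forcing(series)
    if model_type == "GDD":
        return accumulate(series, snow, None)
    if model_type == "GDD_MAX":
        if threshold is None:
            raise ParameterError("GDD_MAX comparison requires a threshold")
        return accumulate(series, snow, threshold)
    raise ParameterError(f"unknown model type {model_type!r}")


def evaluate_model(fit_result: gam.PhenologyModelFit, target: pd.DataFrame,
                   forcings: Dict[int, ForcingSeries],
                   treatment: str, model_type: str) -> pd.DataFrame:
    """Per-year normalized RMSE of a fitted model on a target series.

    ``target`` is a new-flower series (any treatment) with midpoints and
    intervals; forcing at the midpoints is evaluated under the TARGET's own
    temperatures and snowmelt (passed via ``forcings``).  Predictions use
    fixed effects only.  Years whose predicted or observed seasonal total is
    zero are excluded with a logged reason.
    """
    rows = []
    species = str(target["species"].iloc[0])
    location = str(target["location"].iloc[0])
    for year, grp in target.groupby("year"):
        grp = grp.sort_values("date")
        x = forcing_at_many(forcings[int(year)], grp["midpoint"])
        pred = gam.predict_counts(fit_result, x,
                                  grp["interval_days"].to_numpy(float))
        obs = grp["new_flowers"].to_numpy(float)
        if pred.sum() <= 0 or obs.sum() <= 0:
            logger.info("year %s excluded from RMSE (%s total zero)", year,
                        "predicted" if pred.sum() <= 0 else "observed")
            continue
        err = rmse(normalize_seasonal(pred), normalize_seasonal(obs))
        rows.append((species, location, treatment, int(year), model_type,
                     err, len(grp)))
    return pd.DataFrame(rows, columns=["species", "location", "treatment",
                                       "year", "model_type", "rmse",
                                       "n_censuses"])


def compare_models(flowers: pd.DataFrame,
                   temps: Dict[Tuple[str, int], HourlyTemperatureSeries],
                   snow: Dict[Tuple[str, int], SnowSeason],
                   gdd_max_threshold: float,
                   spec: Optional[gam.ModelSpec] = None,
                   model_types: Sequence[str] = MODEL_TYPES) -> pd.DataFrame:
    """Train DOY/GDD/GDD_max models on ambient data and score both treatments.

    ``flowers`` holds the new-flower series for one species x location with
    both treatments; ``temps``/``snow`` are keyed by (treatment, year).  The
    GDD_max cap is the full-data ambient estimate supplied by the caller.
    Forcing for warmed-plot predictions uses warmed temperatures and warmed
    snowmelt dates.
    """
    base = spec or gam.ModelSpec()
    ambient = flowers[flowers["treatment"] == "ambient"]
    years = sorted(ambient["year"].unique())
    results = []
    for mt in model_types:
        thr = gdd_max_threshold if mt == "GDD_MAX" else None
        train_forcings = {
            int(y): _forcing_for(mt, temps[("ambient", int(y))],
                                 snow[("ambient", int(y))], thr)
            for y in years}
        design = gam.build_design(ambient, train_forcings)
        fit_spec = gam.ModelSpec(forcing_type=mt, tmax_threshold=thr,
                                 basis_dimension=base.basis_dimension,
                                 degree=base.degree)
        fit_result = gam.fit(design, fit_spec)
        for trt in ("ambient", "warmed"):
            target = flowers[flowers["treatment"] == trt]
            if target.empty:
                continue
            t_years = sorted(target["year"].unique())
            forcings = {
                int(y): _forcing_for(mt, temps[(trt, int(y))],
                                     snow[(trt, int(y))], thr)
                for y in t_years}
            results.append(evaluate_model(fit_result, target, forcings,
                                          trt, mt))
    return pd.concat(results, ignore_index=True)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Distribution summaries per model type x treatment (box-plot table).

    RMSE rows are one per species x location x year (the averaging unit);
    the summary reports median, quartiles and n per cell.
    """
    if results.empty:
        raise ParameterError("no comparison results to summarize")
    g = results.groupby(["model_type", "treatment"])["rmse"]
    out = g.agg(median="median",
                q1=lambda s: s.quantile(0.25),
                q3=lambda s: s.quantile(0.75),
                n="size").reset_index()
    return out
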
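"""End-to-end pipeline: simulate -> infill -> derive flowers -> estimate
thresholds -> compare models, driven by one config with one master seed.

Every stage writes plain CSV/JSON artifacts into the output directory and the
run finishes with a manifest (paths, sha256 checksums, seeds) plus a
human-readable report echoing the threshold table and the RMSE summary.
Stage outputs are pure functions of (inputs, config, seed): rerunning a
config reproduces identical checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import comparison, gam, io, synthetic, threshold
from .census import prepare_new_flower_series, screen_inclusion
from .errors import ParameterError, PhenocapError
from .temperatures import daily_summaries, infill_gaps, warming_effect
from .types import ClimateScenario, SpeciesResponse, WarmingSpec

logger = logging.getLogger(__name__)

_SCENARIOS = {"high_arctic": synthetic.HIGH_ARCTIC,
              "low_arctic": synthetic.LOW_ARCTIC}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    scenario: ClimateScenario = synthetic.HIGH_ARCTIC
    warming: WarmingSpec = synthetic.DEFAULT_WARMING
    species: List[SpeciesResponse] = field(
        default_factory=lambda: [synthetic.DEFAULT_SPECIES])
    n_years: int = 10
    first_year: int = 2001
    n_plots: int = 24
    census_interval: float = 7.0
    snowmelt_advance_days: float = synthetic.DEFAULT_SNOWMELT_ADVANCE
    jitter_days: float = 0.0
    grid_start: float = 0.5
    grid_stop: float = 20.1
    grid_step: float = 0.2
    basis_dimension: int = 10
    delta_aic_rule: float = 2.0
    min_years: Optional[int] = None   # default: n_years - 2
    min_seasonal_total: int = 5
    stages: Dict[str, bool] = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        return np.round(np.arange(self.grid_start,
                                  self.grid_stop + 1e-9,
                                  self.grid_step), 6)

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "RunConfig":
        run = raw.get("run", {})
        scen_raw = raw.get("scenario", {})
        if isinstance(scen_raw, str):
            scen_raw = {"name": scen_raw}
        name = scen_raw.pop("name", "high_arctic")
        if scen_raw:
            scenario = ClimateScenario(region_label=name, **scen_raw)
        elif name in _SCENARIOS:
            scenario = _SCENARIOS[name]
        else:
            raise ParameterError(f"unknown scenario {name!r}")
        warming = WarmingSpec(**raw.get("warming", {}))
        species = [SpeciesResponse(name=k, **v)
                   for k, v in raw.get("species", {}).items()] or None
        study = raw.get("study", {})
        analysis = raw.get("analysis", {})
        kwargs = dict(
            outdir=base_dir / run.get("outdir", "phenocap_out"),
            seed=int(run.get("seed", 0)),
            scenario=scenario, warming=warming,
            stages=raw.get("stages", {}),
            inputs=raw.get("inputs", {}),
        )
        if species:
            kwargs["species"] = species
        for key in ("n_years", "first_year", "n_plots", "census_interval",
                    "snowmelt_advance_days", "jitter_days"):
            if key in study:
                kwargs[key] = study[key]
        for key in ("grid_start", "grid_stop", "grid_step",
                    "basis_dimension", "delta_aic_rule", "min_years",
                    "min_seasonal_total"):
            if key in analysis:
                kwargs[key] = analysis[key]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = tomllib.loads(text)
        return cls.from_dict(raw, base_dir=path.parent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; return the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}
    report: List[str] = [f"phenocap run (seed={config.seed})", ""]

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    stage = "simulate"
    try:
        if config.stage_enabled("simulate"):
            datasets = {}
            for i, sp in enumerate(config.species):
                datasets[sp.name] = synthetic.simulate_dataset(
                    scenario=config.scenario, warming=config.warming,
                    response=sp, n_years=config.n_years,
                    first_year=config.first_year, n_plots=config.n_plots,
                    census_interval=config.census_interval,
                    snowmelt_advance_days=config.snowmelt_advance_days,
                    jitter_days=config.jitter_days,
                    seed=config.seed * 1000 + i)
            first = next(iter(datasets.values()))
            temps = {(config.scenario.region_label, trt, y): s
                     for (trt, y), s in first.temps.items()}
            snow = {(config.scenario.region_label, trt, y): s
                    for (trt, y), s in first.snow.items()}
            censuses = pd.concat([d.censuses for d in datasets.values()],
                                 ignore_index=True)
            ff = pd.concat([d.first_flower for d in datasets.values()],
                           ignore_index=True)
            truth = pd.concat([d.truth.openings for d in datasets.values()],
                              ignore_index=True)
            io.write_temperatures(temps.values(), out / "temperatures.csv")
            io.write_snowmelt(snow.values(), out / "snowmelt.csv")
            io.write_censuses(censuses, out / "censuses.csv")
            io.write_first_flower(ff, out / "first_flower.csv")
            io.write_truth(truth, out / "truth.csv")
            for n in ("temperatures", "snowmelt", "censuses",
                      "first_flower", "truth"):
                emit(n, out / f"{n}.csv")
        else:
            temps = io.read_temperatures(config.inputs["temperatures"])
            snow = io.read_snowmelt(config.inputs["snowmelt"])
            censuses = io.read_censuses(config.inputs["censuses"])
            ff = (io.read_first_flower(config.inputs["first_flower"])
                  if "first_flower" in config.inputs else None)

        stage = "infill"
        if config.stage_enabled("infill"):
            temps = {k: infill_gaps(s) for k, s in temps.items()}
            io.write_temperatures(temps.values(),
                                  out / "temperatures_infilled.csv")
            emit("temperatures_infilled", out / "temperatures_infilled.csv")
            daily = {k: daily_summaries(s) for k, s in temps.items()}
            effects = []
            for (loc, trt, y) in list(daily):
                if trt != "ambient" or (loc, "warmed", y) not in daily:
                    continue
                eff = warming_effect(daily[(loc, "ambient", y)],
                                     daily[(loc, "warmed", y)])
                eff.insert(0, "location", loc)
                eff.insert(1, "year", y)
                effects.append(eff)
            if effects:
                pd.concat(effects, ignore_index=True).to_csv(
                    out / "warming_effect.csv", index=False)
                emit("warming_effect", out / "warming_effect.csv")

        stage = "derive-flowers"
        flowers = prepare_new_flower_series(censuses, ff)
        io.write_new_flowers(flowers, out / "new_flowers.csv")
        emit("new_flowers", out / "new_flowers.csv")
        min_years = (config.min_years if config.min_years is not None
                     else max(config.n_years - 2, 1))
        included, exclusions = screen_inclusion(
            flowers, min_years=min_years, total_years=config.n_years,
            min_seasonal_total=config.min_seasonal_total)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        emit("exclusions", out / "exclusions.csv")

        stage = "estimate-threshold"
        estimates = []
        profiles = []
        spec = gam.ModelSpec(basis_dimension=config.basis_dimension)
        if config.stage_enabled("threshold"):
            for sp, loc in sorted(included):
                sub = flowers[(flowers["species"] == sp)
                              & (flowers["location"] == loc)
                              & (flowers["treatment"] == "ambient")]
                years = sorted(sub["year"].unique())
                t = {y: temps[(loc, "ambient", y)] for y in years}
                sn = {y: snow[(loc, "ambient", y)] for y in years}
                est = threshold.jackknife_threshold(
                    sub, t, sn, config.grid, spec,
                    delta_aic_rule=config.delta_aic_rule)
                estimates.append(est)
                profiles.append(est.profile.to_frame())
            est_df = threshold.estimates_to_frame(estimates)
            est_df.to_csv(out / "threshold_estimates.csv", index=False)
            emit("threshold_estimates", out / "threshold_estimates.csv")
            if profiles:
                pd.concat(profiles, ignore_index=True).to_csv(
                    out / "threshold_profiles.csv", index=False)
                emit("threshold_profiles", out / "threshold_profiles.csv")
            report.append("Threshold estimates (ambient plots):")
            report.append(est_df.to_string(index=False) if len(est_df)
                          else "  (none)")
            report.append("")

        stage = "compare-models"
        if config.stage_enabled("compare") and estimates:
            results = []
            for est in estimates:
                if not est.saturating:
                    continue
                sub = flowers[(flowers["species"] == est.species)
                              & (flowers["location"] == est.location)]
                t = {(trt, y): temps[(est.location, trt, y)]
                     for trt in ("ambient", "warmed")
                     for y in sorted(sub["year"].unique())
                     if (est.location, trt, y) in temps}
                sn = {(trt, y): snow[(est.location, trt, y)]
                      for (trt, y) in t}
                results.append(comparison.compare_models(
                    sub, t, sn, est.full_data_threshold, spec))
            if results:
                res = pd.concat(results, ignore_index=True)
                res.to_csv(out / "model_rmse.csv", index=False)
                emit("model_rmse", out / "model_rmse.csv")
                summ = comparison.summarize(res)
                summ.to_csv(out / "model_rmse_summary.csv", index=False)
                emit("model_rmse_summary", out / "model_rmse_summary.csv")
                report.append("Normalized RMSE summary (percentage points):")
                report.append(summ.to_string(index=False))
                report.append("")
    except PhenocapError:
        logger.error("pipeline failed in stage %r; partial outputs kept "
                     "in %s", stage, out)
        raise

    manifest = {
        "seed": config.seed,
        "scenario": config.scenario.region_label,
        "species": [sp.name for sp in config.species],
        "artifacts": {k: {"path": v, "sha256": _sha256(Path(v))}
                      for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.txt").write_text("\n".join(report))
    return manifest
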
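# phenocap

Capped thermal-time models of tundra flowering phenology.

Arctic plants track accumulated warmth: the classical growing-degree-day
(GDD) model sums temperatures above 0 °C over snow-free hours and predicts
flowering when a thermal requirement is met. But if development stops
speeding up above some maximum temperature, hot days advance phenology no
more than warm ones — a *saturating* response. `phenocap` detects such
maximum-temperature limits from hourly canopy temperatures and repeated
flower censuses, for researchers analysing tundra warming experiments or
building phenological forecasts.

The core model: per species × location, new flowers per census follow a
penalized Poisson spline GAM in "climate space",

```
count_i ~ Poisson(mu_i)
log mu_i = b0 + f(F(t_i)) + u_year(i) + log(interval_i)
```

where `F` is calendar day (DOY), growing degree days (GDD), or capped
growing degree days

```
GDD_max: an hour contributes 0 if snow-covered or T <= 0,
         min(T, T_max) / 24 degree-days otherwise.
```

Scanning the cap `T_max` over a grid (0.5–20 °C) and tracing the model AIC
yields a threshold profile; an interior minimum at least 2 AIC units below
the uncapped fit, at a cap within the temperatures actually observed (the
95% quantile of snow-free summer hours), is evidence for saturation. A
leave-one-year-out jackknife gives the estimate's median and range, and
normalized RMSE compares how well DOY, GDD and calibrated GDD_max models
trained on ambient plots predict flowering timing in ambient and
experimentally warmed plots.

A synthetic-data generator (hourly temperatures with seasonal, diurnal and
AR(1) structure; passive warming that lifts daily maxima far more than
minima; snowmelt dates; plot-level censuses from a known true cap) provides
ground truth for end-to-end validation. See `docs/methods.md` for model
details, defaults and limitations.

## Worked example

```python
import numpy as np
from phenocap import (simulate_dataset, prepare_new_flower_series,
                      jackknife_threshold)

ds = simulate_dataset(seed=0)            # 10 years, 24 plots, true cap 5 °C
flowers = prepare_new_flower_series(ds.censuses, ds.first_flower)
ambient = flowers[flowers.treatment == "ambient"]

grid = np.round(np.arange(0.5, 20.01, 0.5), 1)
est = jackknife_threshold(ambient, ds.ambient_temps(), ds.ambient_snow(), grid)
print(f"best cap {est.full_data_threshold:.1f} C, "
      f"jackknife {est.min_threshold:.1f}-{est.max_threshold:.1f} C "
      f"(median {est.median_threshold:.1f}), "
      f"saturating={est.saturating}, q95={est.temp_q95:.1f} C")
```

Output:

```
best cap 5.0 C, jackknife 4.5-5.0 C (median 5.0), saturating=True, q95=10.3 C
```

The scan recovers the generator's 5 °C cap exactly on this replicate: the
AIC profile has a deep interior minimum (about 34 units below the uncapped
GDD fit), the jackknife range is tight around it, and the estimate lies
well below the 10.3 °C line under which 95% of snow-free summer hours fall —
a saturating, meaningful threshold.

The same analysis is available from the shell:

```
pheno simulate --outdir study --seed 1
pheno derive-flowers --census study/censuses.csv \
      --firstflower study/first_flower.csv --out study/new_flowers.csv
pheno estimate-threshold --flowers study/new_flowers.csv \
      --temps study/temperatures.csv --snow study/snowmelt.csv \
      --grid 0.5:20:0.5 --out study/thresholds
pheno run --config config.toml      # everything, with manifest + report
```

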
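# Methods

`phenocap` asks whether flowering phenology in cold-region plants stops
responding to temperature above a maximum threshold, and provides the full
analysis chain needed to answer it from hourly canopy temperatures and
repeated flower censuses — together with a synthetic study generator whose
ground truth the chain can be validated against.

## Thermal-time model

Development is measured in growing degree days accumulated hourly above a
0 °C base, with nothing accruing while a plot is snow-covered:

    GDD contribution of an hour =
        0             if snow-covered or T <= 0
        T / 24        otherwise

The capped variant GDD_max replaces `T` by `min(T, T_max)`: hours hotter
than the cap contribute no more than the cap itself. Division by 24 keeps
cumulative forcing in degree-days whatever the temporal resolution; the
spline absorbs any constant rescaling, so model selection is unaffected by
this convention. Snow cover is a per location × treatment date: all hours on
days before the recorded snowmelt day of year contribute zero. Calendar time
(fractional day of year, DOY) is carried through the same interface as the
null "forcing".

## Count model

Per species × location, new flowers per census are derived from plot counts
of non-senesced and senesced flowers (`new_t = open_t + senesced_t −
senesced_{t−1}`, clamped at zero, summed over plots), anchored with a
synthetic zero census two days before the earliest first-flowering date when
a season starts mid-bloom, and assigned midpoint dates and intercensus
intervals (7-day default for the first census of a season).

The seasonal curve is a Poisson generalized additive model:

    count_i ~ Poisson(mu_i)
    log mu_i = b0 + f(forcing at midpoint_i) + u_year(i) + log(interval_i)

`f` is a cubic B-spline (default basis dimension 10, equally spaced knots
over the observed forcing range) with a second-difference penalty — the
P-spline equivalent of a thin-plate smooth; its null space is the linear
trend, and values beyond the fitted range extrapolate linearly. Year
intercepts are random effects, implemented as ridge-penalized coefficients.
The log intercensus interval offsets counts to a per-day intensity.

Fitting is penalized IRLS with step-halving. Both smoothing parameters
(spline wiggliness, year-intercept shrinkage) are selected by minimizing the
conditional AIC

    AIC = −2 loglik + 2 (edf + n_variance_components),
    edf = tr[(X'WX + P)^{-1} X'WX]

with a deterministic Nelder–Mead search on log10 penalties from a fixed
start (bounds 1e−4..1e8, relative IRLS tolerance 1e−9). Mixed-model AIC is
not uniquely defined; what matters for the threshold scan is that the
criterion is computed identically for every candidate forcing, so the
*shape* of AIC profiles is internally consistent. Refitting identical data
reproduces the AIC to well below the 2-unit decision margin. Degenerate
inputs are handled explicitly: all-zero counts are an error, a single year
degrades the random effect to a fixed intercept with a logged note, designs
with fewer rows than basis functions shrink the basis, and a zero-width
forcing range drops the spline term.

## Threshold estimation

The capped model is refit over a grid of candidate caps (default 0.5–20.1 °C
in 0.2 °C steps; the replicate experiments use a coarsened 0.5 °C grid to
keep many-replicate studies tractable) and the AIC traced over the grid is
the threshold profile. The estimate is the profile minimum, ties broken
toward the lower threshold (the conservative direction). Design tables are
cached per candidate cap, so the leave-one-year-out jackknife only drops
rows and refits; it reports the median and range of the per-fold estimates.

Saturation is a reproducible rule in place of visual profile assessment: a
response is *saturating* iff the best capped model beats the uncapped GDD
model by at least 2 AIC units AND the best cap lies at or below the 95%
quantile of snow-free June–August hourly temperatures at the location
(pooled over years, ambient treatment, type-7 quantile convention). Both
margins — against the uncapped fit and against the top-of-grid fit — are
reported for audit. The estimate is *meaningful* when the whole jackknife
range sits below that quantile. A single-point AIC spike of more than 10
units raises an audit flag rather than being selected silently.

## Predictive comparison

Models trained on ambient data (DOY, GDD, and GDD_max at the full-data
ambient cap estimate) predict counts at the target treatment's census
midpoints using fixed effects only, with forcing computed under the
target's own temperatures and snowmelt dates (warmed predictions use warmed
forcing). Predictions and observations are normalized within each year to
percentages of the seasonal total, so the root-mean-squared error (in
percentage points, per species × location × treatment × year) measures
timing rather than abundance. Years with a zero predicted or observed total
are excluded with a logged reason.

## Synthetic data generator

The generator emulates the data-generating structure the analysis assumes,
for a colder high-Arctic and a warmer low-Arctic site:

* **Temperatures** — a Gaussian seasonal curve of daily means (high-Arctic
  default: peak 6 °C on day 200, half-width 30 d over days 150–250;
  low-Arctic: peak 10 °C), evaluated per calendar day so the within-day
  signal is exactly the diurnal sinusoid (amplitude 3 / 4.5 °C, maximum at
  15:00), plus AR(1) noise (marginal SD 2.5 / 3 °C, hourly lag correlation
  0.75 — a daily-mean SD of roughly 1.4 °C, modest relative to real Arctic
  weather).
* **Warming** — a solar-proxy delta: the diurnal sinusoid clipped at zero at
  night, scaled to a 3 °C peak by day and exactly 0.2 °C at night, decaying
  50% across the season (passive chambers are most effective under high
  sun). This reproduces the field signature: daily maxima rise much more
  than daily means, minima barely move.
* **Snowmelt** — Normal(day 163, SD 4) per year, rounded to a day; warming
  advances it by 2 days (a free parameter — field values are not
  established).
* **Flowering** — per plot, bud count ~ Poisson(8); each bud carries a
  lognormal thermal requirement (mean 80 degree-days of capped forcing,
  CV 0.15) and opens the first hour cumulative forcing under the species'
  true cap (default 5 °C) reaches it; flowers remain countable as
  non-senesced for 7 days and as senesced thereafter. The linear-responder
  control uses no cap and a 110 degree-day requirement so flowering still
  peaks midseason. Censuses run weekly (optionally jittered ±2 days) from
  one interval before snowmelt to season end, at 24 plots per treatment.

What the generator does *not* emulate: spatial autocorrelation among plots,
year-to-year variation in flower abundance beyond what snowmelt and weather
induce, overdispersion relative to Poisson, observer error, multi-species
interactions, or mechanistic snow physics. Passing validation therefore
shows the chain is correct and well-calibrated under its own assumptions,
not that real censuses are this clean.

## Validation experiments and problem sizes

The replicate experiments use 10-year, 24-plot studies on the high-Arctic
scenario with the 0.5 °C scan grid: 20 replicates for threshold recovery
(with full jackknife), the linear-responder null, and the predictive
comparison; the reproduce-results script runs 8–10 replicates per
experiment, sized so a single-CPU run stays comfortably interactive.

## Known limitations

* **The day-offset bias.** Under threshold-crossing development, expected
  new flowers per census are proportional to the *degree-day* increment,
  while the count model offsets by interval length in *days*. Capping the
  forcing compresses year-to-year variation in the daily degree-day rate,
  so capped models can genuinely fit a *linear* responder better —
  producing interior AIC minima (often 3–25 units, near ~1.3× the midsummer
  mean temperature) and spurious saturation calls. This is a property of
  the day-offset GAMM procedure itself, not of this implementation: an
  independent mgcv fit of the identical design tables reproduces the same
  profiles. Saturation calls near but below the 95% temperature line should
  therefore be read cautiously; thresholds well inside the observed range
  with deep minima (as recovered in the capped-truth experiments) are
  robust.
* The new-flower derivation double-counts a flower recorded open at one
  census and senesced at a later one; with weekly censuses and ~week-long
  flowers this smears totals by up to a factor ~2 but barely shifts timing,
  which is what the normalized comparisons use.
* The AIC convention is one defensible choice among several for penalized
  mixed models; absolute AIC values are not comparable across conventions,
  only profiles computed under the same convention.
* The threshold is grid-restricted by design; no continuous optimization of
  the cap is attempted, and the base temperature (0 °C) is fixed.
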
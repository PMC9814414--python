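import numpy as np
import pandas as pd
import pytest

from phenocap import gam
from phenocap.errors import CoverageError, DegenerateDataError, ParameterError
from phenocap.gam import ModelSpec, build_design, fit, predict_counts
from phenocap.thermal_time import accumulate, doy_forcing
from phenocap.types import SnowSeason

from conftest import make_series


def hump_design(n_years=5, n_per_year=14, seed=0, peak=60.0, width=15.0,
                amplitude=40.0, interval=7.0):
    """Counts drawn from a known hump-shaped Poisson intensity in forcing
    space; returns (design, truth dict)."""
    rng = np.random.default_rng(seed)
    rows = []
    for y in range(n_years):
        x = np.linspace(5, 120, n_per_year) + rng.uniform(-2, 2, n_per_year)
        mu = amplitude * np.exp(-0.5 * ((x - peak) / width) ** 2) + 0.05
        counts = rng.poisson(mu * interval / 7.0)
        for xi, ci in zip(x, counts):
            rows.append((float(ci), xi, interval, 2000 + y))
    design = pd.DataFrame(rows, columns=["count", "forcing",
                                         "interval_days", "year"])
    return design, {"peak": peak, "width": width, "amplitude": amplitude}


class TestBuildDesign:
    def _flowers(self, midpoint_doys, year=2001):
        base = pd.Timestamp(year=year, month=1, day=1)
        return pd.DataFrame({
            "species": "sp", "location": "loc", "treatment": "ambient",
            "year": year,
            "date": [base + pd.Timedelta(days=d + 2.5) for d in midpoint_doys],
            "new_flowers": [1] * len(midpoint_doys),
            "interval_days": [7.0] * len(midpoint_doys),
            "midpoint": [base + pd.Timedelta(days=d - 1)
                         for d in midpoint_doys],
        })

    def test_doy_covariate_is_fractional_midpoint(self):
        s = make_series(np.full(720, 5.0))
        flowers = self._flowers([155.5, 160.0])
        design = build_design(flowers, {2001: doy_forcing(s)})
        np.testing.assert_allclose(design["forcing"], [155.5, 160.0])

    def test_pre_snowmelt_census_has_zero_gdd(self):
        s = make_series(np.full(720, 5.0))  # doy 150-179
        f = accumulate(s, SnowSeason("loc", "ambient", 2001, 165), None)
        design = build_design(self._flowers([155.0, 170.0]), {2001: f})
        assert design["forcing"].iloc[0] == 0.0
        assert design["forcing"].iloc[1] > 0.0

    def test_row_and_year_bookkeeping(self):
        s1 = make_series(np.full(720, 5.0), year=2001)
        s2 = make_series(np.full(720, 5.0), year=2002)
        flowers = pd.concat([self._flowers([155, 160, 165], 2001),
                             self._flowers([155, 160, 165], 2002)])
        design = build_design(flowers, {2001: doy_forcing(s1),
                                        2002: doy_forcing(s2)})
        assert len(design) == 6
        assert sorted(design["year"].unique()) == [2001, 2002]

    def test_midpoint_outside_span_raises(self):
        s = make_series(np.full(48, 5.0))
        with pytest.raises(CoverageError, match="year 2001"):
            build_design(self._flowers([300.0]), {2001: doy_forcing(s)})


class TestFit:
    def test_refit_identical_aic(self):
        design, _ = hump_design(seed=1)
        a = fit(design)
        b = fit(design)
        assert a.aic == pytest.approx(b.aic, abs=1e-6)

    def test_mean_preservation(self):
        design, _ = hump_design(seed=2)
        res = fit(design)
        assert res.fitted.sum() == pytest.approx(design["count"].sum(),
                                                 rel=0.02)

    def test_offset_contract_doubling_intervals(self):
        design, _ = hump_design(seed=3)
        doubled = design.copy()
        doubled["interval_days"] = 2 * doubled["interval_days"]
        a = fit(design)
        b = fit(doubled)
        x = np.linspace(20, 100, 9)
        per_day_a = predict_counts(a, x, np.ones_like(x))
        per_day_b = predict_counts(b, x, np.ones_like(x))
        np.testing.assert_allclose(per_day_b, per_day_a / 2.0, rtol=0.01)

    def test_aic_invariant_to_covariate_rescaling(self):
        design, _ = hump_design(seed=4)
        scaled = design.copy()
        scaled["forcing"] = scaled["forcing"] * 24.0
        a = fit(design)
        b = fit(scaled)
        assert b.aic == pytest.approx(a.aic, abs=1e-4)

    def test_matches_unpenalized_glm_oracle(self):
        # with both penalties sent to zero the fit must coincide with an
        # ordinary Poisson GLM on the same basis (statsmodels as the oracle)
        import statsmodels.api as sm
        from phenocap.gam import _pirls, _spline_machinery, _poisson_loglik
        design, _ = hump_design(n_years=1, seed=5)
        y = design["count"].to_numpy(float)
        x = design["forcing"].to_numpy(float)
        offset = np.log(design["interval_days"].to_numpy(float))
        _, _, Bc, _, _ = _spline_machinery(x, 8, 3)
        X = np.hstack([np.ones((len(y), 1)), Bc])
        beta, mu, _, conv, _ = _pirls(X, y, offset, np.zeros((X.shape[1],) * 2))
        glm = sm.GLM(y, X, family=sm.families.Poisson(),
                     offset=offset).fit()
        assert conv
        np.testing.assert_allclose(mu, glm.mu, rtol=1e-6)
        assert _poisson_loglik(y, mu) == pytest.approx(glm.llf, abs=1e-6)

    def test_recovers_hump_argmax(self):
        errs = []
        for seed in range(5):
            design, truth = hump_design(seed=seed)
            res = fit(design)
            grid = np.linspace(10, 115, 400)
            fhat = res.spline_value(grid)
            errs.append(abs(grid[np.argmax(fhat)] - truth["peak"]))
        # argmax within one intercensus step of the truth on most replicates
        assert np.median(errs) <= 8.0

    def test_all_zero_counts_rejected(self):
        design, _ = hump_design(seed=6)
        design["count"] = 0.0
        with pytest.raises(DegenerateDataError):
            fit(design)

    def test_single_year_degrades_to_fixed_intercept(self):
        design, _ = hump_design(n_years=1, seed=7)
        res = fit(design)
        assert res.year_effects.size == 0
        assert any("single year" in n for n in res.notes)

    def test_tiny_design_reduces_basis(self):
        design, _ = hump_design(n_years=1, n_per_year=8, seed=8)
        res = fit(design)
        assert any("basis reduced" in n for n in res.notes)


def test_summary_dict_round_trips_through_json():
    import json
    design, _ = hump_design(seed=13)
    res = fit(design)
    d = json.loads(json.dumps(res.summary_dict()))
    assert d["aic"] == pytest.approx(res.aic)
    assert len(d["spline_coef"]) > 0 and d["converged"]


class TestPredict:
    def test_training_predictions_with_random_effects_match_fitted(self):
        design, _ = hump_design(seed=9)
        res = fit(design)
        mu = predict_counts(res, design["forcing"],
                            design["interval_days"],
                            use_random_effects=True,
                            years=design["year"])
        np.testing.assert_allclose(mu, res.fitted, rtol=1e-8)

    def test_interval_ratio_scales_counts(self):
        design, _ = hump_design(seed=10)
        res = fit(design)
        one = predict_counts(res, [50.0], [1.0])
        two = predict_counts(res, [50.0], [2.0])
        assert two[0] == pytest.approx(2 * one[0], rel=1e-9)

    def test_nonpositive_interval_guarded(self):
        design, _ = hump_design(seed=11)
        res = fit(design)
        with pytest.raises(ParameterError):
            predict_counts(res, [50.0], [0.0])

    def test_linear_extrapolation_beyond_range(self):
        design, _ = hump_design(seed=12)
        res = fit(design)
        lo, hi = res.x_range
        f = res.spline_value(np.array([hi, hi + 5.0, hi + 10.0]))
        slope1 = f[1] - f[0]
        slope2 = (f[2] - f[0]) / 2
        assert slope1 == pytest.approx(slope2, rel=1e-9, abs=1e-12)
        assert res.extrapolation_mask(np.array([hi + 5.0]))[0]
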
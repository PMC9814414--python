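import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phenocap.census import (aggregate_plots, anchor_first_census,
                             assign_midpoints, derive_all,
                             derive_new_flowers, prepare_new_flower_series,
                             screen_inclusion)
from phenocap.errors import StructuralError
from phenocap.synthetic import simulate_censuses, simulate_hourly_temperatures
from phenocap.thermal_time import accumulate
from phenocap.types import ClimateScenario, SnowSeason, SpeciesResponse


def obs_frame(rows, plot="P1", species="sp", location="loc",
              treatment="ambient", year=2001):
    return pd.DataFrame([{
        "species": species, "plot": plot, "location": location,
        "treatment": treatment,
        "date": pd.Timestamp(year=year, month=1, day=1)
                + pd.Timedelta(days=doy - 1),
        "n_open": o, "n_senesced": s} for doy, o, s in rows])


class TestDeriveNewFlowers:
    def test_worked_example(self):
        df = obs_frame([(160, 1, 1), (167, 3, 2)])
        out = derive_new_flowers(df)
        # first census: 1 + (1 - 0) = 2; second: 3 + (2 - 1) = 4
        assert list(out["new_flowers"]) == [2, 4]

    def test_all_zero(self):
        out = derive_new_flowers(obs_frame([(160, 0, 0), (167, 0, 0)]))
        assert list(out["new_flowers"]) == [0, 0]

    def test_no_change_yields_zero(self):
        out = derive_new_flowers(obs_frame([(160, 0, 5), (167, 0, 5)]))
        assert list(out["new_flowers"]) == [5, 0]

    def test_negative_clamped_and_raw_kept(self):
        out = derive_new_flowers(obs_frame([(160, 0, 5), (167, 0, 2)]))
        assert list(out["new_flowers"]) == [5, 0]
        assert list(out["new_flowers_raw"]) == [5, -3]

    def test_unsorted_raises(self):
        df = obs_frame([(167, 1, 0), (160, 0, 0)])
        with pytest.raises(StructuralError):
            derive_new_flowers(df)

    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 30)),
                    min_size=1, max_size=12))
    def test_telescoping_identity(self, pairs):
        # raw new-flower sums telescope to open total + senesced change
        sen = np.cumsum([s for _, s in pairs])  # make senesced non-decreasing
        rows = [(150 + 3 * i, o, int(sv))
                for i, ((o, _), sv) in enumerate(zip(pairs, sen))]
        out = derive_new_flowers(obs_frame(rows))
        lhs = out["new_flowers_raw"].sum()
        rhs = (out["n_open"].sum()
               + out["n_senesced"].iloc[-1])  # first lag is 0
        assert lhs == rhs


class TestAggregate:
    def test_identical_plots_sum(self):
        plots = pd.concat([
            derive_new_flowers(obs_frame([(160, 0, 0), (167, 1, 0),
                                          (174, 0, 0)], plot=f"P{i}"))
            for i in range(24)], ignore_index=True)
        agg = aggregate_plots(plots)
        assert list(agg["new_flowers"]) == [0, 24, 0]
        assert agg["n_plots"].iloc[0] == 24

    def test_single_plot_identity(self):
        one = derive_new_flowers(obs_frame([(160, 2, 0), (167, 1, 2)]))
        agg = aggregate_plots(one)
        assert list(agg["new_flowers"]) == list(one["new_flowers"])

    def test_mismatched_schedules_raise(self):
        a = derive_new_flowers(obs_frame([(160, 1, 0)], plot="P1"))
        b = derive_new_flowers(obs_frame([(161, 1, 0)], plot="P2"))
        with pytest.raises(StructuralError):
            aggregate_plots(pd.concat([a, b], ignore_index=True))

    def test_aggregation_commutes_with_derivation(self):
        rng = np.random.default_rng(4)
        plots = []
        for i in range(5):
            sen = np.cumsum(rng.integers(0, 4, size=6))
            rows = [(150 + 7 * t, int(rng.integers(0, 6)), int(sen[t]))
                    for t in range(6)]
            plots.append(obs_frame(rows, plot=f"P{i}"))
        raw = pd.concat(plots, ignore_index=True)
        a = aggregate_plots(derive_all(raw))["new_flowers"].to_numpy()
        summed = (raw.groupby("date", as_index=False)
                  [["n_open", "n_senesced"]].sum())
        summed[["species", "plot", "location", "treatment"]] = \
            ["sp", "ALL", "loc", "ambient"]
        b = derive_new_flowers(summed)["new_flowers"].to_numpy()
        np.testing.assert_array_equal(a, b)


class TestAnchor:
    def _agg(self, first_count):
        df = obs_frame([(170, first_count, 0), (177, 2, first_count)])
        return aggregate_plots(derive_all(df))

    def _ff(self, doy):
        return pd.DataFrame([{
            "species": "sp", "plot": "P1", "location": "loc",
            "treatment": "ambient", "year": 2001,
            "first_flower_date": pd.Timestamp("2001-01-01")
                                 + pd.Timedelta(days=doy - 1)}])

    def test_zero_first_census_unchanged(self):
        agg = self._agg(0)
        out = anchor_first_census(agg, None)
        pd.testing.assert_frame_equal(out, agg)

    def test_two_day_rule(self):
        out = anchor_first_census(self._agg(7), self._ff(170))
        assert len(out) == 3
        assert out.iloc[0]["anchored"]
        assert out.iloc[0]["new_flowers"] == 0
        assert out.iloc[0]["date"].dayofyear == 168

    def test_anchor_not_before_census_rejected(self):
        with pytest.raises(StructuralError):
            anchor_first_census(self._agg(7), self._ff(173))

    def test_missing_first_flower_table_rejected(self):
        with pytest.raises(StructuralError):
            anchor_first_census(self._agg(7), None)


class TestMidpoints:
    def test_worked_example(self):
        df = obs_frame([(168, 0, 0), (175, 3, 0), (183, 1, 3)])
        out = assign_midpoints(aggregate_plots(derive_all(df)))
        assert list(out["interval_days"]) == [7.0, 7.0, 8.0]
        mid_doy = (out["midpoint"].dt.dayofyear
                   + out["midpoint"].dt.hour / 24.0)
        np.testing.assert_allclose(mid_doy, [164.5, 171.5, 179.0])

    def test_single_census_default_interval(self):
        df = obs_frame([(170, 2, 0)])
        out = assign_midpoints(aggregate_plots(derive_all(df)))
        assert out["interval_days"].iloc[0] == 7.0
        assert (out["date"] - out["midpoint"]).iloc[0] == pd.Timedelta(
            days=3.5)

    def test_duplicate_dates_raise(self):
        df = aggregate_plots(derive_all(obs_frame([(170, 1, 0), (177, 0, 1)])))
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(StructuralError):
            assign_midpoints(dup)


class TestScreening:
    def _year(self, counts, year, treatment="ambient"):
        rows = [(150 + 7 * i, int(c), 0) for i, c in enumerate(counts)]
        df = obs_frame(rows, year=year, treatment=treatment)
        return aggregate_plots(derive_all(df))

    def test_interior_peak_included(self):
        series = pd.concat([self._year([0, 2, 9, 3, 0], 2000 + y)
                            for y in range(10)], ignore_index=True)
        included, excl = screen_inclusion(series, min_years=10,
                                          total_years=10)
        assert ("sp", "loc") in included and excl.empty

    def test_boundary_peak_not_determinable(self):
        series = pd.concat([self._year([9, 3, 0], 2000 + y)
                            for y in range(10)], ignore_index=True)
        included, excl = screen_inclusion(series, min_years=10,
                                          total_years=10)
        assert included == set()
        assert "determinable peak" in excl.iloc[0]["reason"]

    def test_nine_of_thirteen_years_excluded(self):
        good = [self._year([0, 2, 9, 3, 0], 2000 + y) for y in range(9)]
        bad = [self._year([9, 3, 0, 0, 0], 2009 + y) for y in range(4)]
        series = pd.concat(good + bad, ignore_index=True)
        included, _ = screen_inclusion(series, min_years=10, total_years=13)
        assert included == set()

    def test_low_total_not_determinable(self):
        series = pd.concat([self._year([0, 1, 2, 1, 0], 2000 + y)
                            for y in range(10)], ignore_index=True)
        included, _ = screen_inclusion(series, min_years=10, total_years=10,
                                       min_seasonal_total=5)
        assert included == set()


class TestAgainstTruth:
    def test_derived_totals_match_truth_openings(self):
        # senescence equal to the census interval: every opened flower is
        # non-senesced at exactly one census, so derived new-flower totals
        # must reproduce the generator's ground truth exactly
        scen = ClimateScenario("loc", 150, 230, 7.0, 190.0, 25.0, 3.0, 0.7,
                               2.0, 158.0, 2.0)
        sp = SpeciesResponse("sp", 5.0, 60.0, 0.2, 6.0, 7.0)
        s = simulate_hourly_temperatures(scen, 2001, seed=3)
        snow = SnowSeason("loc", "ambient", 2001, 158)
        forcing = accumulate(s, snow, sp.true_tmax)
        cen, opened = simulate_censuses(forcing, sp, 10, 7.0, seed=3,
                                        record_senesced=False)
        flowers = prepare_new_flower_series(cen)
        assert flowers["new_flowers"].sum() == len(opened)
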
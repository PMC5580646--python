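"""Percentile classification and the category-level statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import thermomort as tm
from thermomort import categories


def make_pairs_frame(responses, exposures=None, start="2000-01-01"):
    n = len(responses)
    dates = pd.date_range(start, periods=n, freq="D")
    if exposures is None:
        exposures = np.zeros(n)
    return pd.DataFrame({"date": dates, "age_group": "all", "window": 1,
                         "lag": 0, "exposure": np.asarray(exposures, float),
                         "response": np.asarray(responses, float)})


def series_1_100():
    idx = pd.date_range("2000-01-01", periods=100, freq="D")
    return pd.Series(np.arange(1.0, 101.0), index=idx)


class TestPercentileBreaks:
    def test_median_linear_interpolation(self):
        br = categories.percentile_breaks(series_1_100(), levels=(0.5,))
        assert br.breakpoints[0] == pytest.approx(50.5)

    def test_default_levels_make_twelve_categories(self):
        br = categories.percentile_breaks(series_1_100())
        assert len(br.levels) == 11
        assert br.n_categories == 12
        assert len(br.category_ranges()) == 12

    def test_breakpoints_monotone_in_level(self):
        rng = np.random.default_rng(0)
        idx = pd.date_range("2000-01-01", periods=4000, freq="D")
        s = pd.Series(rng.normal(size=4000), index=idx)
        br = categories.percentile_breaks(s)
        assert (np.diff(br.breakpoints) >= 0).all()

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2000-01-01", periods=500, freq="D")
        vals = rng.normal(size=500)
        a = categories.percentile_breaks(pd.Series(vals, index=idx))
        b = categories.percentile_breaks(
            pd.Series(rng.permutation(vals), index=idx))
        assert np.allclose(a.breakpoints, b.breakpoints)

    def test_constant_series_degenerate_warning(self):
        idx = pd.date_range("2000-01-01", periods=200, freq="D")
        with pytest.warns(UserWarning, match="degenerate"):
            br = categories.percentile_breaks(pd.Series(3.0, index=idx))
        assert (br.breakpoints == 3.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            categories.percentile_breaks(
                pd.Series([], dtype=float, index=pd.DatetimeIndex([])))


class TestClassify:
    @pytest.fixture()
    def breaks(self):
        return categories.percentile_breaks(series_1_100())

    def test_value_at_breakpoint_goes_low(self, breaks):
        b1 = breaks.breakpoints[0]
        assert categories.classify(b1, breaks) == 1
        assert categories.classify(b1 + 1e-9, breaks) == 2

    def test_values_outside_data_range_still_classified(self, breaks):
        assert categories.classify(-1e6, breaks) == 1
        assert categories.classify(1e6, breaks) == 12

    def test_nan_rejected(self, breaks):
        with pytest.raises(ValueError, match="NaN"):
            categories.classify(np.nan, breaks)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(value=st.floats(-10, 120))
    def test_matches_linear_scan_oracle(self, value):
        br = categories.percentile_breaks(series_1_100())
        cat = 1
        for b in br.breakpoints:
            if value > b:
                cat += 1
        assert categories.classify(value, br) == cat

    def test_partition_property(self, breaks):
        rng = np.random.default_rng(3)
        vals = rng.uniform(-20, 130, 5000)
        cats = categories.classify(vals, breaks)
        assert cats.min() >= 1 and cats.max() <= 12
        assert len(cats) == 5000


class TestCategorySummary:
    def test_simple_mean(self):
        pairs = make_pairs_frame([0.0, 10.0, 20.0])
        br = categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))
        out = categories.category_summary(pairs, br)
        assert out.loc[out.category == 1, "mean_rm"].iloc[0] == 10.0
        assert out["n_days"].sum() == 3

    def test_equal_responses_zero_width_ci(self):
        pairs = make_pairs_frame([7.0] * 10)
        br = categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))
        out = categories.category_summary(pairs, br)
        row = out[out.category == 1].iloc[0]
        assert row["mean_rm"] == 7.0
        assert row["ci_low"] == row["ci_high"] == 7.0

    def test_empty_category_row_present(self):
        rng = np.random.default_rng(4)
        pairs = make_pairs_frame(rng.normal(size=200), rng.normal(size=200))
        br = categories.percentile_breaks(
            pd.Series(rng.normal(size=1000),
                      index=pd.date_range("2000-01-01", periods=1000)))
        out = categories.category_summary(pairs, br)
        assert len(out) == 12
        assert out["n_days"].sum() == 200

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(5)
        exp = rng.normal(size=2000)
        pairs = make_pairs_frame(rng.normal(size=2000), exp)
        br = categories.percentile_breaks(
            pd.Series(exp, index=pd.date_range("1990-01-01", periods=2000)))
        out = categories.category_summary(pairs, br)
        ok = out.dropna(subset=["ci_low"])
        assert ((ok["ci_low"] <= ok["mean_rm"])
                & (ok["mean_rm"] <= ok["ci_high"])).all()

    def test_pooled_mean_is_weighted_subperiod_combination(self):
        rng = np.random.default_rng(6)
        n = 4000
        exp = rng.normal(size=n)
        pairs = make_pairs_frame(rng.normal(size=n), exp, start="1972-01-01")
        br = categories.percentile_breaks(
            pd.Series(exp, index=pd.date_range("1972-01-01", periods=n)))
        mid = pairs["date"].iloc[n // 2]
        a = pairs[pairs["date"] <= mid]
        b = pairs[pairs["date"] > mid]
        pooled = categories.category_summary(pairs, br)
        sa = categories.category_summary(a, br)
        sb = categories.category_summary(b, br)
        for k in range(1, 13):
            na = sa.loc[sa.category == k, "n_days"].iloc[0]
            nb = sb.loc[sb.category == k, "n_days"].iloc[0]
            if na + nb == 0:
                continue
            ma = sa.loc[sa.category == k, "mean_rm"].iloc[0] if na else 0.0
            mb = sb.loc[sb.category == k, "mean_rm"].iloc[0] if nb else 0.0
            combined = (na * ma + nb * mb) / (na + nb)
            assert pooled.loc[pooled.category == k, "mean_rm"].iloc[0] \
                == pytest.approx(combined, abs=1e-10)


class TestCategoryTrend:
    def test_exact_linear_slope(self):
        n = 3653  # one decade of days
        t = np.arange(n) / 3652.5
        pairs = make_pairs_frame(-3.9 * t, np.zeros(n))
        br = categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))
        out = categories.category_trend(pairs, br)
        row = out[out.category == 1].iloc[0]
        assert row["trend"] == pytest.approx(-3.9, abs=1e-9)
        assert row["stars"] == "***"

    def test_constant_responses_zero_slope(self):
        pairs = make_pairs_frame([5.0] * 100)
        br = categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))
        out = categories.category_trend(pairs, br)
        assert out[out.category == 1]["trend"].iloc[0] == 0.0

    def test_shuffled_responses_ci_covers_zero(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=400)
        br = categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))
        covered = 0
        n_shuffles = 1000
        for _ in range(n_shuffles):
            pairs = make_pairs_frame(rng.permutation(base))
            row = categories.category_trend(pairs, br).iloc[0]
            covered += row["trend_ci_low"] <= 0 <= row["trend_ci_high"]
        assert covered >= 0.93 * n_shuffles

    def test_sparse_category_flagged(self):
        pairs = make_pairs_frame([1.0, 2.0])
        br = categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))
        out = categories.category_trend(pairs, br)
        assert np.isnan(out[out.category == 1]["trend"].iloc[0])


class TestSubperiodCompare:
    def _breaks(self):
        return categories.PercentileBreaks(
            levels=(0.5,), breakpoints=np.array([100.0]),
            data_min=-1.0, data_max=1.0, reference_period=(None, None))

    def test_identical_samples_t_zero_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 200)
        pairs = make_pairs_frame(np.concatenate([vals, vals]),
                                 start="1990-01-01")
        mid = pairs["date"].iloc[len(vals) - 1]
        out = categories.subperiod_compare(
            pairs, self._breaks(),
            period_a=(pairs["date"].iloc[0], mid),
            period_b=(mid + pd.Timedelta(days=1), pairs["date"].iloc[-1]))
        row = out[out.category == 1].iloc[0]
        assert row["welch_t"] == pytest.approx(0.0, abs=1e-12)
        assert row["welch_p"] == pytest.approx(1.0)

    def test_welch_equals_pooled_t_for_equal_n_and_var(self):
        rng = np.random.default_rng(8)
        xa = rng.normal(0, 1, 300)
        xb = rng.normal(0.5, 1, 300)
        # algebraic identity: equal sizes make Welch t == pooled t
        welch = stats.ttest_ind(xa, xb, equal_var=False)
        pooled = stats.ttest_ind(xa, xb, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-12)

    def test_step_change_detected(self):
        rng = np.random.default_rng(9)
        a = rng.normal(18.0, 5.0, 400)
        b = rng.normal(9.0, 5.0, 400)
        pairs = make_pairs_frame(np.concatenate([a, b]), start="1990-01-01")
        mid = pairs["date"].iloc[399]
        out = categories.subperiod_compare(
            pairs, self._breaks(),
            period_a=(pairs["date"].iloc[0], mid),
            period_b=(mid + pd.Timedelta(days=1), pairs["date"].iloc[-1]))
        row = out[out.category == 1].iloc[0]
        assert row["welch_p"] < 1e-6
        assert row["mean_a"] == pytest.approx(18.0, abs=1.0)
        assert row["mean_b"] == pytest.approx(9.0, abs=1.0)
        assert row["stars"] == "***"

    def test_small_subperiod_flagged_undefined(self):
        pairs = make_pairs_frame([1.0, 2.0, 3.0], start="1990-01-01")
        out = categories.subperiod_compare(
            pairs, self._breaks(),
            period_a=(pd.Timestamp("1990-01-01"), pd.Timestamp("1990-01-01")),
            period_b=(pd.Timestamp("1990-01-02"), pd.Timestamp("1990-01-03")))
        assert np.isnan(out[out.category == 1]["welch_p"].iloc[0])


def test_build_category_table_shape(short_dataset):
    weather, pop, deaths, _ = short_dataset
    from thermomort import baseline, exposure
    popw = pop.pivot(index="year", columns="age_group", values="population")
    pop_daily = baseline.interpolate_population(
        popw["all"], start=deaths.index[0], end=deaths.index[-1])
    rm = baseline.relative_mortality_pipeline(deaths["all"], pop_daily)
    idx = weather["mean"].loc[rm.index[0]:rm.index[-1]]
    br = categories.percentile_breaks(idx)
    pairs = exposure.make_pairs(rm, idx, 2, 1)
    mid = pd.Timestamp("1994-01-01")
    table = categories.build_category_table(
        pairs, br, period_a=(rm.index[0], mid),
        period_b=(mid + pd.Timedelta(days=1), rm.index[-1]))
    assert len(table) == 12
    assert table["n_days"].sum() == len(pairs)
    md = categories.format_table_markdown(table)
    assert "p < 0.001" in md and md.count("|") > 50
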
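"""Percentile-category statistics of relative mortality.

The thermal-index distribution over the whole study period is cut at the
levels 1, 2.5, 5, 10, 25, 50, 75, 90, 95, 97.5 and 99 percent, defining
twelve categories.  Per category and age group this module computes the
mean relative mortality with a 95% t-interval, its linear time trend in
%/decade, and a sub-period comparison (Welch two-sample t-test with
Shapiro-Wilk normality checks), i.e. the columns of a classic
percentile-category excess-mortality table.

No multiple-testing correction is applied anywhere; the tables report
per-category tests as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import DAYS_PER_DECADE

DEFAULT_LEVELS = (0.01, 0.025, 0.05, 0.10, 0.25, 0.50,
                  0.75, 0.90, 0.95, 0.975, 0.99)

#: default sub-periods: two 21-year spans with the boundary year excluded
SUBPERIOD_A = (pd.Timestamp("1972-01-01"), pd.Timestamp("1992-12-31"))
SUBPERIOD_B = (pd.Timestamp("1994-01-01"), pd.Timestamp("2014-12-31"))

SHAPIRO_MAX_N = 5000


@dataclass(frozen=True)
class PercentileBreaks:
    """Empirical quantile breakpoints defining the exposure categories."""

    levels: tuple
    breakpoints: np.ndarray
    data_min: float
    data_max: float
    reference_period: tuple

    @property
    def n_categories(self) -> int:
        return len(self.levels) + 1

    def category_ranges(self) -> list[tuple[float, float]]:
        edges = [self.data_min, *self.breakpoints, self.data_max]
        return [(edges[k], edges[k + 1]) for k in range(self.n_categories)]

    def category_labels(self) -> list[str]:
        pct = [f"{100 * p:g}" for p in self.levels]
        labels = [f"0–{pct[0]}"]
        labels += [f"{pct[k]}–{pct[k + 1]}" for k in range(len(pct) - 1)]
        labels.append(f"{pct[-1]}–100")
        return labels


def percentile_breaks(index, levels=DEFAULT_LEVELS,
                      quantile_method: str = "linear") -> PercentileBreaks:
    """Empirical quantiles of a thermal index over the whole period.

    The breakpoints are computed once over the full study period and are
    reused unchanged when the data are later split into sub-periods.
    """
    from .exposure import _as_series

    series = _as_series(index).dropna()
    if len(series) == 0:
        raise ValueError("cannot compute percentiles of an empty series")
    levels = tuple(float(p) for p in levels)
    if any(not 0 < p < 1 for p in levels):
        raise ValueError("levels must lie strictly between 0 and 1")
    if sorted(levels) != list(levels):
        raise ValueError("levels must be increasing")
    if len(series) < 1.0 / min(levels):
        warnings.warn(
            f"only {len(series)} observations for a {min(levels):g} quantile; "
            "extreme breakpoints are unstable", stacklevel=2)
    values = series.to_numpy(dtype=float)
    breaks = np.quantile(values, levels, method=quantile_method)
    if np.unique(breaks).size < breaks.size:
        warnings.warn("degenerate categories: repeated breakpoints", stacklevel=2)
    return PercentileBreaks(
        levels=levels, breakpoints=breaks,
        data_min=float(values.min()), data_max=float(values.max()),
        reference_period=(series.index.min(), series.index.max()))


def classify(values, breaks: PercentileBreaks):
    """Category id (1..n) for exposure values; intervals are right-closed.

    Category 1 is (-inf, b1]; category k is (b_{k-1}, b_k]; the top
    category is (b_last, +inf).  Values outside the reference data range
    are still classified, which matters when whole-period breakpoints are
    reused on sub-periods.
    """
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("cannot classify NaN exposure values")
    cats = np.searchsorted(breaks.breakpoints, arr, side="left") + 1
    return cats if cats.ndim else int(cats)


def _t_ci(x: np.ndarray, confidence: float = 0.95):
    n = len(x)
    m = float(np.mean(x))
    if n < 2:
        return m, np.nan, np.nan
    sd = float(np.std(x, ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n)
    return m, m - half, m + half


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _with_categories(pairs: pd.DataFrame, breaks: PercentileBreaks) -> pd.DataFrame:
    out = pairs.copy()
    out["category"] = classify(out["exposure"].to_numpy(), breaks)
    return out


def category_summary(pairs: pd.DataFrame, breaks: PercentileBreaks,
                     confidence: float = 0.95) -> pd.DataFrame:
    """Mean relative mortality per category with a t-based CI.

    Empty categories yield a row with ``n_days=0`` and NaN statistics;
    singleton categories report the mean with an undefined CI.
    """
    tagged = _with_categories(pairs, breaks)
    ranges = breaks.category_ranges()
    labels = breaks.category_labels()
    rows = []
    for k in range(1, breaks.n_categories + 1):
        resp = tagged.loc[tagged["category"] == k, "response"].to_numpy()
        if len(resp):
            mean, lo, hi = _t_ci(resp, confidence)
        else:
            mean = lo = hi = np.nan
        rows.append({
            "category": k, "label": labels[k - 1],
            "range_low": ranges[k - 1][0], "range_high": ranges[k - 1][1],
            "n_days": len(resp), "mean_rm": mean,
            "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)


def category_trend(pairs: pd.DataFrame, breaks: PercentileBreaks,
                   annual_means: bool = False) -> pd.DataFrame:
    """Linear time trend (%/decade) of relative mortality per category.

    By default the regression uses the daily pair values; with
    ``annual_means=True`` it regresses the annual category means instead
    (a variant that downweights years rich in that category).
    """
    tagged = _with_categories(pairs, breaks)
    rows = []
    for k in range(1, breaks.n_categories + 1):
        sub = tagged[tagged["category"] == k]
        if annual_means and len(sub) >= 3:
            grouped = sub.groupby(sub["date"].dt.year)["response"].mean()
            x = (grouped.index.to_numpy(dtype=float)
                 - float(grouped.index.min())) / 10.0
            y = grouped.to_numpy()
        else:
            x = ((sub["date"] - pairs["date"].min()).dt.days.to_numpy()
                 / DAYS_PER_DECADE)
            y = sub["response"].to_numpy()
        if len(y) < 3 or np.ptp(x) == 0:
            rows.append({"category": k, "n_days": len(sub), "trend": np.nan,
                         "trend_ci_low": np.nan, "trend_ci_high": np.nan,
                         "trend_p": np.nan, "stars": ""})
            continue
        res = stats.linregress(x, y)
        if res.stderr == 0.0:
            lo = hi = res.slope
            p = 1.0 if res.slope == 0.0 else 0.0
        else:
            half = stats.t.ppf(0.975, len(y) - 2) * res.stderr
            lo, hi, p = res.slope - half, res.slope + half, res.pvalue
        rows.append({"category": k, "n_days": len(sub),
                     "trend": float(res.slope), "trend_ci_low": float(lo),
                     "trend_ci_high": float(hi), "trend_p": float(p),
                     "stars": _stars(p)})
    return pd.DataFrame(rows)


def _shapiro_p(x: np.ndarray, rng_seed: int = 0) -> float:
    if len(x) < 3:
        return np.nan
    if len(x) > SHAPIRO_MAX_N:
        rng = np.random.default_rng(rng_seed)
        x = rng.choice(x, SHAPIRO_MAX_N, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def subperiod_compare(pairs: pd.DataFrame, breaks: PercentileBreaks,
                      period_a: tuple = SUBPERIOD_A,
                      period_b: tuple = SUBPERIOD_B,
                      confidence: float = 0.95) -> pd.DataFrame:
    """Welch comparison of per-category means between two sub-periods.

    Uses the category breakpoints of the whole period for both
    sub-periods.  Categories where either sub-period has fewer than two
    days are flagged with NaN test statistics.
    """
    tagged = _with_categories(pairs, breaks)
    a0, a1 = pd.Timestamp(period_a[0]), pd.Timestamp(period_a[1])
    b0, b1 = pd.Timestamp(period_b[0]), pd.Timestamp(period_b[1])
    in_a = tagged["date"].between(a0, a1)
    in_b = tagged["date"].between(b0, b1)
    rows = []
    for k in range(1, breaks.n_categories + 1):
        xa = tagged.loc[in_a & (tagged["category"] == k), "response"].to_numpy()
        xb = tagged.loc[in_b & (tagged["category"] == k), "response"].to_numpy()
        mean_a, lo_a, hi_a = _t_ci(xa, confidence) if len(xa) else (np.nan,) * 3
        mean_b, lo_b, hi_b = _t_ci(xb, confidence) if len(xb) else (np.nan,) * 3
        if len(xa) >= 2 and len(xb) >= 2:
            welch = stats.ttest_ind(xa, xb, equal_var=False)
            t, p, df = float(welch.statistic), float(welch.pvalue), float(welch.df)
        else:
            t = p = df = np.nan
        rows.append({
            "category": k,
            "n_a": len(xa), "mean_a": mean_a, "ci_low_a": lo_a, "ci_high_a": hi_a,
            "n_b": len(xb), "mean_b": mean_b, "ci_low_b": lo_b, "ci_high_b": hi_b,
            "welch_t": t, "welch_df": df, "welch_p": p, "stars": _stars(p),
            "shapiro_p_a": _shapiro_p(xa), "shapiro_p_b": _shapiro_p(xb),
        })
    return pd.DataFrame(rows)


def build_category_table(pairs: pd.DataFrame, breaks: PercentileBreaks,
                         period_a: tuple = SUBPERIOD_A,
                         period_b: tuple = SUBPERIOD_B) -> pd.DataFrame:
    """Full per-category table: mean (CI), trend, sub-period comparison."""
    summary = category_summary(pairs, breaks)
    trend = category_trend(pairs, breaks).drop(columns=["n_days"])
    compare = subperiod_compare(pairs, breaks, period_a, period_b)
    table = summary.merge(trend, on="category", suffixes=("", "_trend"))
    table = table.merge(compare, on="category", suffixes=("", "_cmp"))
    if "age_group" in pairs.columns and len(pairs):
        table.insert(0, "age_group", pairs["age_group"].iloc[0])
    return table


def format_table_markdown(table: pd.DataFrame, index_name: str = "index") -> str:
    """Render a category table as a compact markdown report section."""

    def fmt(v, nd=1):
        return "" if not np.isfinite(v) else f"{v:.{nd}f}"

    lines = []
    age = table["age_group"].iloc[0] if "age_group" in table.columns else "all"
    lines.append(f"### {index_name} — age group {age}")
    lines.append("")
    lines.append("| Percentile | Range (degC) | n | Mean RM % (95% CI) | "
                 "Trend %/decade (95% CI) | | Mean A % | Mean B % | t-test |")
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for _, r in table.iterrows():
        lines.append(
            f"| {r['label']} | {fmt(r['range_low'])}, {fmt(r['range_high'])} "
            f"| {int(r['n_days'])} "
            f"| {fmt(r['mean_rm'])} ({fmt(r['ci_low'])}, {fmt(r['ci_high'])}) "
            f"| {fmt(r['trend'])} ({fmt(r['trend_ci_low'])}, "
            f"{fmt(r['trend_ci_high'])}) | {r['stars']} "
            f"| {fmt(r['mean_a'])} ({fmt(r['ci_low_a'])}, {fmt(r['ci_high_a'])}) "
            f"| {fmt(r['mean_b'])} ({fmt(r['ci_low_b'])}, {fmt(r['ci_high_b'])}) "
            f"| {r['stars_cmp']} |")
    lines.append("")
    lines.append("Significance: * p < 0.05, ** p < 0.01, *** p < 0.001. "
                 "No multiple-testing correction applied.")
    lines.append("")
    return "\n".join(lines)


def moving_block_bootstrap_ci(responses: np.ndarray, block: int = 14,
                              n_boot: int = 1000, confidence: float = 0.95,
                              rng_seed: int = 0):
    """Moving-block bootstrap CI for a category mean (sensitivity option).

    Plain t-intervals ignore day-to-day autocorrelation of relative
    mortality; this resamples blocks of consecutive pairs instead.
    """
    x = np.asarray(responses, dtype=float)
    n = len(x)
    if n < 2:
        return float(np.mean(x)) if n else np.nan, np.nan, np.nan
    block = min(block, n)
    rng = np.random.default_rng(rng_seed)
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=(n_boot, n_blocks))
    means = np.empty(n_boot)
    for b in range(n_boot):
        sample = np.concatenate([x[s:s + block] for s in starts[b]])[:n]
        means[b] = sample.mean()
    alpha = 1.0 - confidence
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(np.mean(x)), float(lo), float(hi)
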
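"""Gaussian-baseline relative mortality.

Implements the Koppe-Jendritzky construction: expected mortality is the
daily mortality rate convolved with a 365-day Gaussian kernel, and
relative mortality is the percent deviation of the observed rate from
that baseline.  The baseline keeps the seasonal cycle but removes
day-to-day variability and long-term trends, so relative mortality is
stationary by construction and comparable across decades of population
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def ensure_daily(series: pd.Series, name: str = "series") -> pd.Series:
    """Validate a contiguous daily series with finite values."""
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError(f"{name} must have a DatetimeIndex")
    if len(series) == 0:
        raise ValueError(f"{name} is empty")
    diffs = np.diff(series.index.asi8)
    day = 86_400_000_000_000
    if len(diffs) and not np.all(diffs == day):
        bad = series.index[1:][diffs != day]
        raise ValueError(f"{name} has gaps or duplicates near {bad[0].date()}")
    if not np.all(np.isfinite(series.to_numpy(dtype=float))):
        raise ValueError(f"{name} contains non-finite values")
    return series


def interpolate_population(annual: pd.Series,
                           start: pd.Timestamp | None = None,
                           end: pd.Timestamp | None = None) -> pd.Series:
    """Daily population by linear interpolation between mid-year anchors.

    ``annual`` is indexed by calendar year.  Each annual value anchors at
    July 2 (the middle of the year); days outside the first/last anchor
    hold the endpoint value flat.
    """
    if len(annual) < 2:
        raise ValueError("need at least two annual population values to interpolate")
    years = np.asarray(sorted(annual.index))
    values = annual.loc[years].to_numpy(dtype=float)
    anchors = pd.DatetimeIndex([pd.Timestamp(int(y), 7, 2) for y in years])
    if start is None:
        start = pd.Timestamp(int(years[0]), 1, 1)
    if end is None:
        end = pd.Timestamp(int(years[-1]), 12, 31)
    dates = pd.date_range(start, end, freq="D")
    daily = np.interp(dates.asi8, anchors.asi8, values)
    return pd.Series(daily, index=dates, name=getattr(annual, "name", "population"))


def daily_rate(deaths: pd.Series, population: pd.Series) -> pd.Series:
    """Daily mortality per 100,000 persons: rate = deaths / pop * 1e5."""
    common = deaths.index.intersection(population.index)
    if len(common) == 0:
        raise ValueError("deaths and population share no dates")
    d = deaths.loc[common].astype(float)
    p = population.loc[common].astype(float)
    if (p <= 0).any():
        bad = common[(p <= 0).to_numpy()][0]
        raise ValueError(f"non-positive population on {bad.date()}")
    out = d / p * 100_000.0
    out.name = "rate_per_100k"
    return out


@dataclass(frozen=True)
class GaussianKernel:
    """Symmetric truncated Gaussian filter over +-half_width days."""

    half_width: int
    sigma: float
    weights: np.ndarray

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1


def build_kernel(total_width_days: int = 365,
                 sigma_days: float = 15.0) -> GaussianKernel:
    """Truncated, renormalized Gaussian kernel of odd total width.

    The default is a 365-day window with sigma = 15 days: the annual
    harmonic passes with gain 0.967, so the baseline keeps the seasonal
    cycle, while white day-to-day noise variance is cut roughly 50-fold.
    A much wider sigma would flatten the seasonal cycle out of the
    baseline and leak it into relative mortality.
    """
    if total_width_days % 2 == 0:
        raise ValueError(f"total_width_days must be odd, got {total_width_days}")
    if total_width_days < 3:
        raise ValueError("total_width_days must be >= 3")
    if not sigma_days > 0:
        raise ValueError("sigma_days must be > 0")
    half = (total_width_days - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (offsets / sigma_days) ** 2)
    w /= w.sum()
    return GaussianKernel(half_width=half, sigma=float(sigma_days), weights=w)


def expected_mortality(rate: pd.Series, kernel: GaussianKernel) -> pd.Series:
    """Centered Gaussian convolution; edges are dropped, not renormalized.

    The first and last ``half_width`` days have no full window and are
    removed, shortening the series from both ends.
    """
    ensure_daily(rate, "rate")
    if len(rate) <= kernel.width:
        raise ValueError(
            f"series of {len(rate)} days is not longer than the "
            f"{kernel.width}-day kernel")
    smoothed = np.convolve(rate.to_numpy(dtype=float), kernel.weights,
                           mode="valid")
    dates = rate.index[kernel.half_width:len(rate) - kernel.half_width]
    return pd.Series(smoothed, index=dates, name="expected")


def relative_mortality(observed: pd.Series, expected: pd.Series) -> pd.Series:
    """Percent deviation of observed from expected: 100 (obs - exp) / exp."""
    common = observed.index.intersection(expected.index)
    if len(common) == 0:
        raise ValueError("observed and expected share no dates")
    obs = observed.loc[common].astype(float)
    exp = expected.loc[common].astype(float)
    if (exp <= 0).any():
        bad = common[(exp <= 0).to_numpy()][0]
        raise ValueError(f"expected mortality must be positive; violated on "
                         f"{bad.date()}")
    rm = 100.0 * (obs - exp) / exp
    rm.name = "relative_mortality_pct"
    return rm


def trim_to_full_years(series: pd.Series) -> pd.Series:
    """Restrict a daily series to its fully covered calendar years."""
    ensure_daily(series, "series")
    first, last = series.index[0], series.index[-1]
    y0 = first.year if (first.month, first.day) == (1, 1) else first.year + 1
    y1 = last.year if (last.month, last.day) == (12, 31) else last.year - 1
    if y1 < y0:
        raise ValueError(
            f"coverage {first.date()}..{last.date()} contains no complete "
            "calendar year")
    return series.loc[pd.Timestamp(y0, 1, 1):pd.Timestamp(y1, 12, 31)]


DAYS_PER_DECADE = 3652.5


@dataclass(frozen=True)
class TrendEstimate:
    """OLS linear time trend in units of the series per decade."""

    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    stderr: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def linear_trend(series: pd.Series, confidence: float = 0.95) -> TrendEstimate:
    """OLS of value on elapsed decades, with a t-based confidence interval."""
    if len(series) < 3:
        raise ValueError("need at least 3 points for a trend")
    x = (series.index - series.index[0]).days.to_numpy() / DAYS_PER_DECADE
    if np.ptp(x) == 0:
        raise ValueError("time axis is constant")
    y = series.to_numpy(dtype=float)
    res = stats.linregress(x, y)
    n = len(series)
    if not np.isfinite(res.stderr) or res.stderr == 0.0:
        # perfectly (or degenerately) linear data: CI collapses
        p = 1.0 if res.slope == 0.0 else 0.0
        return TrendEstimate(float(res.slope), float(res.slope),
                             float(res.slope), p, 0.0, n)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    half = tcrit * res.stderr
    return TrendEstimate(float(res.slope), float(res.slope - half),
                         float(res.slope + half), float(res.pvalue),
                         float(res.stderr), n)


def relative_mortality_pipeline(deaths: pd.Series,
                                population_daily: pd.Series,
                                kernel: GaussianKernel | None = None,
                                smooth_rates: bool = True) -> pd.Series:
    """Deaths + daily population -> trimmed relative-mortality series.

    By default the per-100,000 rate is smoothed, making the result
    invariant to population size; set ``smooth_rates=False`` to smooth
    raw counts instead (sensitivity variant).
    """
    kernel = kernel or build_kernel()
    target = daily_rate(deaths, population_daily) if smooth_rates else deaths.astype(float)
    expected = expected_mortality(target, kernel)
    rm = relative_mortality(target, expected)
    return trim_to_full_years(rm)
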
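"""Thermal-index preparation and exposure-response pairing.

Turns sub-daily observations into daily index values, averages gridded
series spatially, and builds the pairings between a thermal index and
relative mortality: the primary same-day-plus-next-day design (window 2,
lag 1) and the 7/14-day heat-wave / cold-spell windows without lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLAUSIBLE_RANGE = (-80.0, 60.0)  # degC, warn outside

INDEX_KINDS = ("tavg", "tmax", "tmin", "pet_daily_mean", "pet_06utc", "pet_12utc")


@dataclass
class ThermalIndexSeries:
    """A daily thermal index (degC) with provenance metadata."""

    series: pd.Series
    index_kind: str = "tavg"
    provenance: str = "station"

    def __post_init__(self) -> None:
        if self.index_kind not in INDEX_KINDS:
            raise ValueError(f"unknown index_kind {self.index_kind!r}")
        vals = self.series.dropna().to_numpy(dtype=float)
        if len(vals) and not np.all(np.isfinite(vals)):
            raise ValueError("thermal index contains non-finite values")
        lo, hi = PLAUSIBLE_RANGE
        if len(vals) and ((vals < lo).any() or (vals > hi).any()):
            warnings.warn(
                f"{self.index_kind} values outside the plausible range "
                f"[{lo}, {hi}] degC", stacklevel=2)


def _as_series(index) -> pd.Series:
    return index.series if isinstance(index, ThermalIndexSeries) else index


def daily_mean_from_subdaily(subdaily: pd.Series,
                             min_obs: int = 6,
                             index_kind: str = "tavg") -> ThermalIndexSeries:
    """Unweighted daily mean of time-stamped observations.

    Days with fewer than ``min_obs`` observations (default 6 of the 8
    three-hourly synoptic slots) are marked missing (NaN).
    """
    if len(subdaily) == 0:
        raise ValueError("sub-daily series is empty")
    grouped = subdaily.groupby(subdaily.index.normalize())
    means = grouped.mean()
    counts = grouped.size()
    means[counts < min_obs] = np.nan
    means.index.name = "date"
    return ThermalIndexSeries(means, index_kind=index_kind, provenance="station")


def spatial_average(cells, index_kind: str = "tavg") -> ThermalIndexSeries:
    """Unweighted per-day mean over grid cells.

    ``cells`` is a DataFrame (date x cell) or an iterable of daily
    Series; all cells must cover identical dates.
    """
    if isinstance(cells, pd.DataFrame):
        frame = cells
    else:
        series = list(cells)
        if not series:
            raise ValueError("no cell series given")
        base = series[0].index
        for s in series[1:]:
            if not s.index.equals(base):
                missing = base.symmetric_difference(s.index)
                raise ValueError(
                    f"cell series dates are misaligned; first mismatch "
                    f"{missing[0].date()}")
        frame = pd.concat(series, axis=1)
    if frame.shape[1] == 0:
        raise ValueError("no cell series given")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise ValueError(f"cell series dates are misaligned; first mismatch "
                         f"{bad.date()}")
    avg = frame.mean(axis=1)
    avg.name = index_kind
    return ThermalIndexSeries(avg, index_kind=index_kind, provenance="grid-average")


def make_pairs(relmort: pd.Series,
               index,
               window_days: int = 2,
               lag_days: int = 1,
               age_group: str = "all",
               centered: bool = False) -> pd.DataFrame:
    """Pair a thermal index with (windowed) relative mortality.

    Primary design (``window_days=2, lag_days=1``): the exposure on day d
    is paired with the mean relative mortality over d and d+1.  With
    ``lag_days=0`` and a window larger than one day, both exposure and
    response are w-day trailing means labeled by the window's last day
    (``centered=True`` centers the window on its label instead).

    Returns a DataFrame with columns
    ``date, age_group, window, lag, exposure, response``.
    """
    idx = _as_series(index)
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    if lag_days > 0 and window_days != lag_days + 1:
        raise ValueError(
            "with a positive lag the response window spans the exposure day "
            f"through lag_days after it; pass window_days={lag_days + 1}")
    # NaN (missing) index days propagate through the window means and the
    # affected pairs are dropped at the end
    common = relmort.index.intersection(idx.index)
    if len(common) < window_days:
        raise ValueError(
            f"overlap of {len(common)} days is shorter than the "
            f"{window_days}-day window")
    rm = relmort.loc[common].astype(float)
    ix = idx.loc[common].astype(float)

    if lag_days > 0:
        # forward mean over the exposure day and the next lag_days days
        resp = rm.rolling(window_days).mean().shift(-(window_days - 1))
        expo = ix
    elif window_days == 1:
        resp, expo = rm, ix
    else:
        resp = rm.rolling(window_days, center=centered).mean()
        expo = ix.rolling(window_days, center=centered).mean()

    out = pd.DataFrame({
        "date": common,
        "age_group": age_group,
        "window": window_days,
        "lag": lag_days,
        "exposure": expo.to_numpy(),
        "response": resp.to_numpy(),
    })
    out = out.dropna(subset=["exposure", "response"]).reset_index(drop=True)
    return out


@dataclass
class PairSet:
    """Pairs per age group for one (index kind, window, lag) design."""

    window: int
    lag: int
    index_kind: str
    frames: dict = field(default_factory=dict)

    def combined(self) -> pd.DataFrame:
        return pd.concat(self.frames.values(), ignore_index=True)
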
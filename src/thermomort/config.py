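"""Configuration objects for the synthetic-data generator.

The generator emulates a 43-year northern-European daily mortality /
weather setting: a growing, ageing population of roughly 1.0 to 1.6
million; declining age-specific death rates; a winter-peaking seasonal
mortality cycle; and a J-shaped excess-mortality response to daily mean
temperature, optionally changing between sub-periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd

AGE_GROUPS = ("lt65", "65_74", "ge75")
#: groups reported downstream; "all" and "ge65" are derived sums
REPORTED_AGE_GROUPS = ("all", "lt65", "65_74", "ge75", "ge65")


@dataclass(frozen=True)
class ExcessCurve:
    """One branch of the excess-mortality response g(T), in percent.

    ``side="hot"``:  g(T) = step + slope * (T - threshold)  for T > threshold
    ``side="cold"``: g(T) = step + slope * (threshold - T)  for T < threshold
    and g(T) = 0 on the neutral side of the threshold.

    ``slope`` is %/degC moving away from the threshold, ``step`` a flat
    jump (%) applied as soon as the threshold is crossed.
    """

    threshold: float
    slope: float = 0.0
    step: float = 0.0
    side: str = "hot"

    def __post_init__(self) -> None:
        if self.side not in ("hot", "cold"):
            raise ValueError(f"side must be 'hot' or 'cold', got {self.side!r}")
        for name in ("threshold", "slope", "step"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"ExcessCurve.{name} must be finite, got {v!r}")
        if self.slope < 0:
            raise ValueError("slope must be >= 0 (magnitude away from threshold)")

    def __call__(self, temperature):
        import numpy as np

        t = np.asarray(temperature, dtype=float)
        if self.side == "hot":
            excess = np.where(t > self.threshold,
                              self.step + self.slope * (t - self.threshold), 0.0)
        else:
            excess = np.where(t < self.threshold,
                              self.step + self.slope * (self.threshold - t), 0.0)
        return excess if excess.ndim else float(excess)


@dataclass(frozen=True)
class SubperiodCurve:
    """An excess curve active from ``start`` (inclusive) onwards.

    ``start=None`` means "from the beginning of the simulated range".
    """

    curve: ExcessCurve
    start: pd.Timestamp | None = None


def _default_hot_curves() -> tuple[SubperiodCurve, ...]:
    # Heat excess begins in the warm tail and roughly halves across the
    # 1993 boundary, mirroring the observed weakening of heat sensitivity.
    return (
        SubperiodCurve(ExcessCurve(threshold=17.0, slope=2.7, side="hot"), None),
        SubperiodCurve(ExcessCurve(threshold=17.0, slope=1.35, side="hot"),
                       pd.Timestamp("1993-01-01")),
    )


def _default_cold_curves() -> tuple[SubperiodCurve, ...]:
    return (SubperiodCurve(ExcessCurve(threshold=-10.0, slope=0.3, side="cold"), None),)


@dataclass
class GeneratorConfig:
    """Study-scale defaults for the synthetic daily mortality dataset.

    Weather is a seasonal cycle plus linear warming plus AR(1) noise.
    Deaths are Poisson with a winter-peaking seasonal factor and a
    temperature-driven excess acting at ``effect_lag_days``.
    """

    start_date: pd.Timestamp = pd.Timestamp("1971-01-01")
    end_date: pd.Timestamp = pd.Timestamp("2015-12-31")
    n_gridcells: int = 1

    # weather: Helsinki-like daily mean temperature
    temp_mean_annual: float = 5.0          # degC
    temp_seasonal_amplitude: float = 12.0  # degC, peak-to-mean
    temp_trend: float = 0.4                # degC per decade
    temp_ar1_coefficient: float = 0.8      # daily anomaly persistence
    temp_noise_sd: float = 2.4             # degC innovation sd
    temp_peak_doy: int = 196               # mid-July
    diurnal_amplitude: float = 4.0         # degC, 3-hourly output only

    # population and age structure
    population_start: float = 1_000_000.0
    population_end: float = 1_600_000.0
    age_share_start: Mapping[str, float] = field(
        default_factory=lambda: {"lt65": 0.909, "65_74": 0.061, "ge75": 0.030})
    age_share_end: Mapping[str, float] = field(
        default_factory=lambda: {"lt65": 0.835, "65_74": 0.100, "ge75": 0.065})

    # baseline death rates, per 100,000 persons per day, per age group
    base_rate_start: Mapping[str, float] = field(
        default_factory=lambda: {"lt65": 1.05, "65_74": 8.5, "ge75": 33.0})
    base_rate_end: Mapping[str, float] = field(
        default_factory=lambda: {"lt65": 0.50, "65_74": 4.5, "ge75": 16.5})

    seasonal_mortality_amplitude: float = 0.15  # fractional winter peak
    mortality_peak_doy: int = 14                # mid-January

    hot_curves: Sequence[SubperiodCurve] = field(default_factory=_default_hot_curves)
    cold_curves: Sequence[SubperiodCurve] = field(default_factory=_default_cold_curves)
    age_excess_scale: Mapping[str, float] = field(
        default_factory=lambda: {"lt65": 0.8, "65_74": 1.0, "ge75": 1.3})

    effect_lag_days: int = 0
    overdispersion: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.start_date = pd.Timestamp(self.start_date)
        self.end_date = pd.Timestamp(self.end_date)
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        if self.n_gridcells < 1:
            raise ValueError("n_gridcells must be >= 1")
        for name in ("temp_mean_annual", "temp_seasonal_amplitude", "temp_trend",
                     "temp_ar1_coefficient", "temp_noise_sd",
                     "population_start", "population_end",
                     "seasonal_mortality_amplitude", "overdispersion"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"GeneratorConfig.{name} must be finite, got {v!r}")
        for name in ("temp_seasonal_amplitude", "temp_noise_sd",
                     "seasonal_mortality_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"GeneratorConfig.{name} must be >= 0")
        if abs(self.temp_ar1_coefficient) >= 1:
            raise ValueError("|temp_ar1_coefficient| must be < 1")
        if self.population_start <= 0 or self.population_end <= 0:
            raise ValueError("populations must be positive")
        if self.effect_lag_days < 0:
            raise ValueError("effect_lag_days must be >= 0")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        for mapping_name in ("base_rate_start", "base_rate_end"):
            rates = getattr(self, mapping_name)
            for g in AGE_GROUPS:
                if g not in rates:
                    raise ValueError(f"{mapping_name} missing age group {g!r}")
                if not (rates[g] > 0 and math.isfinite(rates[g])):
                    raise ValueError(f"{mapping_name}[{g!r}] must be positive finite")
        for mapping_name in ("age_share_start", "age_share_end"):
            shares = getattr(self, mapping_name)
            total = sum(shares.get(g, 0.0) for g in AGE_GROUPS)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{mapping_name} shares must sum to 1, got {total}")
        self.hot_curves = _check_subperiods("hot_curves", self.hot_curves,
                                            self.start_date)
        self.cold_curves = _check_subperiods("cold_curves", self.cold_curves,
                                             self.start_date)

    def to_dict(self) -> dict:
        """JSON-friendly echo of the configuration."""
        d = asdict(self)
        d["start_date"] = str(self.start_date.date())
        d["end_date"] = str(self.end_date.date())
        for key in ("hot_curves", "cold_curves"):
            d[key] = [
                {**asdict(sp.curve),
                 "from": None if sp.start is None else str(sp.start.date())}
                for sp in getattr(self, key)
            ]
        for key in ("age_share_start", "age_share_end",
                    "base_rate_start", "base_rate_end", "age_excess_scale"):
            d[key] = dict(getattr(self, key))
        return d


def _check_subperiods(name: str,
                      curves: Sequence[SubperiodCurve],
                      start_date: pd.Timestamp) -> tuple[SubperiodCurve, ...]:
    """Normalize sub-period curves: sorted, first starting at the range start."""
    if not curves:
        return ()
    norm = [SubperiodCurve(sp.curve,
                           start_date if sp.start is None else pd.Timestamp(sp.start))
            for sp in curves]
    norm.sort(key=lambda sp: sp.start)
    if norm[0].start > start_date:
        raise ValueError(
            f"{name}: first sub-period starts {norm[0].start.date()}, after the "
            f"simulated range start {start_date.date()}; sub-periods must "
            "partition the date range")
    starts = [sp.start for sp in norm]
    if len(set(starts)) != len(starts):
        raise ValueError(f"{name}: duplicate sub-period start dates")
    return tuple(norm)


def piecewise_excess(curves: Sequence[SubperiodCurve],
                     dates: pd.DatetimeIndex,
                     temperature) -> "pd.Series":
    """Evaluate the sub-period-dependent excess g(T(d)) along ``dates``."""
    import numpy as np

    out = np.zeros(len(dates))
    if not curves:
        return pd.Series(out, index=dates)
    starts = [sp.start for sp in curves]
    # which curve is active on each date
    idx = np.searchsorted(pd.DatetimeIndex(starts).asi8, dates.asi8, side="right") - 1
    t = np.asarray(temperature, dtype=float)
    for k, sp in enumerate(curves):
        mask = idx == k
        if mask.any():
            out[mask] = sp.curve(t[mask])
    return pd.Series(out, index=dates)
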
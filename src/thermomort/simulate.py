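"""Synthetic weather, population and death-count generator.

Produces daily series with the statistical structure the downstream
analysis assumes — seasonal winter-high mortality, declining baseline
rates, growing and ageing population, warming AR(1) weather, and a
configurable temperature-driven excess — together with the ground truth
needed to test recovery of the injected signal.

All randomness flows from ``GeneratorConfig.rng_seed`` through named
:class:`numpy.random.SeedSequence` sub-streams, so identical configs give
bit-identical outputs regardless of which generator function is called
first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import (AGE_GROUPS, GeneratorConfig, piecewise_excess)

_STREAM_WEATHER = 0
_STREAM_DEATHS = 1

THREE_HOURLY_SLOTS = np.arange(0, 24, 3)


def _dates(config: GeneratorConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.start_date, config.end_date, freq="D")


def _seasonal_cycle(dates: pd.DatetimeIndex, amplitude: float, peak_doy: int) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    return amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _elapsed_decades(dates: pd.DatetimeIndex) -> np.ndarray:
    return (dates - dates[0]).days.to_numpy() / 3652.5


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1): x_t = phi x_{t-1} + eps_t, eps ~ N(0, sd^2)."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, size=n)
    # start from the stationary distribution
    eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi ** 2))
    return signal.lfilter([1.0], [1.0, -phi], eps)


def generate_weather(config: GeneratorConfig,
                     three_hourly: bool = False):
    """Generate daily mean temperature (degC) for each grid cell.

    Returns a DataFrame with one column per cell (``cell_0`` ...) and a
    ``mean`` column holding the spatial average; the ``mean`` column is
    what the single-index analysis consumes.  With ``three_hourly=True``
    additionally returns a 3-hourly Series for cell 0 whose daily mean
    equals the daily value exactly (a mean-zero diurnal cosine over the
    eight synoptic hours is added).
    """
    dates = _dates(config)
    season = _seasonal_cycle(dates, config.temp_seasonal_amplitude,
                             config.temp_peak_doy)
    trend = config.temp_trend * _elapsed_decades(dates)
    base = config.temp_mean_annual + season + trend

    cells = {}
    for cell in range(config.n_gridcells):
        ss = np.random.SeedSequence((config.rng_seed, _STREAM_WEATHER, cell))
        rng = np.random.default_rng(ss)
        noise = _ar1(len(dates), config.temp_ar1_coefficient,
                     config.temp_noise_sd, rng)
        cells[f"cell_{cell}"] = base + noise
    weather = pd.DataFrame(cells, index=dates)
    weather["mean"] = weather[list(cells)].mean(axis=1)
    weather.index.name = "date"

    if not three_hourly:
        return weather

    daily = weather["cell_0"].to_numpy()
    hours = THREE_HOURLY_SLOTS
    # diurnal cosine peaking at 15h; mean over the 8 slots is exactly zero
    diurnal = config.diurnal_amplitude * np.cos(2 * np.pi * (hours - 15) / 24.0)
    diurnal = diurnal - diurnal.mean()
    stamps = (dates.to_numpy()[:, None]
              + hours[None, :].astype("timedelta64[h]")).ravel()
    values = (daily[:, None] + diurnal[None, :]).ravel()
    subdaily = pd.Series(values, index=pd.DatetimeIndex(stamps), name="temperature")
    return weather, subdaily


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Annual population by age group, linear between the endpoints.

    Returns a tidy frame with columns ``year``, ``age_group``
    (including ``all``) and ``population``.  Age-group shares shift
    linearly between their start and end values, emulating a population
    whose elderly share roughly doubles over four decades.
    """
    years = np.arange(config.start_date.year, config.end_date.year + 1)
    frac = (years - years[0]) / max(years[-1] - years[0], 1)
    total = config.population_start + frac * (config.population_end
                                              - config.population_start)
    rows = []
    for g in AGE_GROUPS:
        share = (config.age_share_start[g]
                 + frac * (config.age_share_end[g] - config.age_share_start[g]))
        for y, p in zip(years, total * share):
            rows.append((int(y), g, float(p)))
    for y, p in zip(years, total):
        rows.append((int(y), "all", float(p)))
    out = pd.DataFrame(rows, columns=["year", "age_group", "population"])
    return out.sort_values(["age_group", "year"]).reset_index(drop=True)


def _daily_population(config: GeneratorConfig,
                      population: pd.DataFrame,
                      dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Piecewise-linear daily population per age group, mid-year anchors."""
    from .baseline import interpolate_population

    cols = {}
    for g in AGE_GROUPS:
        annual = (population[population.age_group == g]
                  .set_index("year")["population"])
        cols[g] = interpolate_population(annual, start=dates[0], end=dates[-1])
    return pd.DataFrame(cols, index=dates)


@dataclass
class GeneratorTruth:
    """Ground truth retained for recovery testing.

    ``expected_deaths`` is the noiseless Poisson mean per age group
    (including the derived ``all``); ``baseline_deaths`` the same with the
    temperature effect switched off; ``excess_pct`` the injected g(T(d-lag))
    per age group in percent.
    """

    config: GeneratorConfig
    seed: int
    expected_deaths: pd.DataFrame
    baseline_deaths: pd.DataFrame
    excess_pct: pd.DataFrame

    def true_excess(self, age_group: str, temperature, dates) -> pd.Series:
        """Evaluate the injected excess curve g (%) for given exposures."""
        dates = pd.DatetimeIndex(dates)
        scale = self.config.age_excess_scale.get(age_group, 1.0)
        if age_group == "all":
            scale = 1.0  # approximate: group scales are death-weighted downstream
        hot = piecewise_excess(self.config.hot_curves, dates, temperature)
        cold = piecewise_excess(self.config.cold_curves, dates, temperature)
        return scale * (hot + cold)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "mean_daily_deaths": {
                g: float(self.expected_deaths[g].mean())
                for g in self.expected_deaths.columns
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def generate_deaths(config: GeneratorConfig,
                    weather: pd.DataFrame | pd.Series,
                    population: pd.DataFrame):
    """Draw Poisson daily death counts per age group.

    mean(d, a) = pop(d,a)/1e5 * rate(d,a) * (1 + seasonal cycle)
                 * (1 + g_a(T(d - lag)) / 100)

    Returns ``(deaths, truth)`` where ``deaths`` has columns
    ``all, lt65, 65_74, ge75`` (``all`` is the exact sum of the groups)
    and ``truth`` is a :class:`GeneratorTruth`.
    """
    dates = _dates(config)
    temp = weather["mean"] if isinstance(weather, pd.DataFrame) else weather
    missing = dates.difference(temp.index)
    if len(missing):
        raise ValueError(
            f"weather does not cover the configured dates: missing "
            f"{missing[0].date()}..{missing[-1].date()} ({len(missing)} days)")
    temp = temp.reindex(dates)

    pop = _daily_population(config, population, dates)
    decades = _elapsed_decades(dates)
    n_decades = decades[-1] if decades[-1] > 0 else 1.0
    season = 1.0 + _seasonal_cycle(dates, config.seasonal_mortality_amplitude,
                                   config.mortality_peak_doy)

    lagged = temp.shift(config.effect_lag_days).bfill().to_numpy()
    hot = piecewise_excess(config.hot_curves, dates, lagged)
    cold = piecewise_excess(config.cold_curves, dates, lagged)
    g_base = (hot + cold).to_numpy()

    expected, baseline, excess = {}, {}, {}
    counts = {}
    for j, g in enumerate(AGE_GROUPS):
        rate = (config.base_rate_start[g]
                + (config.base_rate_end[g] - config.base_rate_start[g])
                * decades / n_decades)
        mu0 = pop[g].to_numpy() / 1e5 * rate * season
        scale = config.age_excess_scale.get(g, 1.0)
        g_a = scale * g_base
        mu = np.maximum(mu0 * (1.0 + g_a / 100.0), 0.0)
        baseline[g] = mu0
        expected[g] = mu
        excess[g] = g_a
        rng = np.random.default_rng(
            np.random.SeedSequence((config.rng_seed, _STREAM_DEATHS, j)))
        if config.overdispersion > 1.0:
            # gamma-mixed Poisson (negative binomial) with Var = odisp * mean
            shape = mu / (config.overdispersion - 1.0)
            mixed = np.where(mu > 0, rng.gamma(np.maximum(shape, 1e-12))
                             * (config.overdispersion - 1.0), 0.0)
            counts[g] = rng.poisson(mixed)
        else:
            counts[g] = rng.poisson(mu)

    deaths = pd.DataFrame(counts, index=dates)
    deaths.insert(0, "all", deaths[list(AGE_GROUPS)].sum(axis=1))
    deaths.index.name = "date"

    exp_df = pd.DataFrame(expected, index=dates)
    exp_df.insert(0, "all", exp_df[list(AGE_GROUPS)].sum(axis=1))
    base_df = pd.DataFrame(baseline, index=dates)
    base_df.insert(0, "all", base_df[list(AGE_GROUPS)].sum(axis=1))
    exc_df = pd.DataFrame(excess, index=dates)
    truth = GeneratorTruth(config=config, seed=config.rng_seed,
                           expected_deaths=exp_df, baseline_deaths=base_df,
                           excess_pct=exc_df)
    return deaths, truth


def simulate_dataset(config: GeneratorConfig):
    """Run the full generator: weather, population, deaths and truth."""
    weather = generate_weather(config)
    population = generate_population(config)
    deaths, truth = generate_deaths(config, weather, population)
    return weather, population, deaths, truth


def write_dataset(outdir: str | Path,
                  weather: pd.DataFrame,
                  population: pd.DataFrame,
                  deaths: pd.DataFrame,
                  truth: GeneratorTruth | None = None) -> dict:
    """Write the generated dataset as plain CSV files (+ truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cell_cols = [c for c in weather.columns if c.startswith("cell_")]
    tidy = weather[cell_cols].copy()
    tidy.index.name = "date"
    long = tidy.reset_index().melt("date", var_name="cell_id", value_name="value")
    long["variable"] = "tavg"
    long = long.sort_values(["cell_id", "date"]).reset_index(drop=True)
    paths["weather"] = outdir / "weather.csv"
    long.to_csv(paths["weather"], index=False, date_format="%Y-%m-%d",
                float_format="%.6f")

    paths["population"] = outdir / "population.csv"
    population.to_csv(paths["population"], index=False, float_format="%.2f")

    md = deaths.reset_index().melt("date", var_name="age_group",
                                   value_name="deaths")
    md = md.sort_values(["age_group", "date"]).reset_index(drop=True)
    paths["mortality"] = outdir / "mortality.csv"
    md.to_csv(paths["mortality"], index=False, date_format="%Y-%m-%d")

    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths


def read_weather_csv(path: str | Path, variable: str = "tavg") -> pd.DataFrame:
    """Read the tidy weather CSV back into a date x cell frame with 'mean'."""
    df = pd.read_csv(path, parse_dates=["date"])
    df = df[df["variable"] == variable]
    wide = df.pivot(index="date", columns="cell_id", values="value")
    wide.columns.name = None
    wide["mean"] = wide.mean(axis=1)
    return wide


def read_mortality_csv(path: str | Path) -> pd.DataFrame:
    """Read the tidy mortality CSV into a date x age_group count frame."""
    df = pd.read_csv(path, parse_dates=["date"])
    wide = df.pivot(index="date", columns="age_group", values="deaths")
    wide.columns.name = None
    return wide


def read_population_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
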
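import numpy as np
import pandas as pd
import pytest

import thermomort as tm


@pytest.fixture(scope="session")
def short_config():
    """Fast 8-year generator config with both excess branches active."""
    return tm.GeneratorConfig(start_date="1990-01-01", end_date="1997-12-31",
                              rng_seed=7)


@pytest.fixture(scope="session")
def short_dataset(short_config):
    return tm.simulate_dataset(short_config)


@pytest.fixture(scope="session")
def no_effect_config():
    return tm.GeneratorConfig(start_date="1990-01-01", end_date="1997-12-31",
                              hot_curves=(), cold_curves=(), rng_seed=7)


@pytest.fixture()
def daily_series():
    def _make(values, start="2000-01-01", name="x"):
        values = np.asarray(values, dtype=float)
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.Series(values, index=idx, name=name)
    return _make


@pytest.fixture()
def clean_inputs():
    """A tiny internally consistent mortality/population/weather triple."""
    dates = pd.date_range("2000-01-01", periods=10, freq="D")
    mortality = pd.DataFrame({"lt65": 5, "65_74": 4, "ge75": 11}, index=dates)
    mortality.insert(0, "all", mortality.sum(axis=1))
    population = pd.DataFrame({
        "year": [2000, 2000, 2000, 2000],
        "age_group": ["all", "lt65", "65_74", "ge75"],
        "population": [1_000_000, 900_000, 60_000, 40_000],
    })
    weather = pd.DataFrame({"cell_0": np.linspace(-5, 5, 10)}, index=dates)
    return mortality, population, weather
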
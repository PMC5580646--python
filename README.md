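# thermomort

Temperature–mortality exposure-response analysis for daily death-count
time series, built for epidemiologists and biometeorologists studying
heat- and cold-related mortality over multi-decade periods.

Long mortality records are dominated by demographic change: growing and
ageing populations, falling baseline death rates, and a strong seasonal
cycle. `thermomort` removes all of that with the Koppe–Jendritzky
construction — *expected mortality* is the daily mortality rate
(per 100,000) convolved with a 365-day Gaussian filter, and *relative
mortality* is the percentage deviation from it:

    rm(d) = 100 · (m(d) − E[m](d)) / E[m](d),   E[m] = m ∗ G₃₆₅

`rm` is stationary by construction (no trend, no seasonal cycle), so
responses to thermal extremes can be compared across decades. The
package then relates `rm` to a thermal index *T* (daily mean air
temperature, or a precomputed thermal-comfort index such as PET):

* **Percentile categories** — *T* is cut at its whole-period 1, 2.5, 5,
  10, 25, 50, 75, 90, 95, 97.5 and 99th percentiles into 12 categories;
  per category and age group the analysis reports mean `rm` with 95% CI,
  its linear trend (%/decade), sub-period means (1972–1992 vs
  1994–2014 by default), and a Welch two-sample t-test with
  Shapiro–Wilk normality checks.
* **Smooth curves** — penalized-spline (GAM-style) exposure-response
  curves `rm = f(T)` with pointwise 95% bands, per period.
* **Pairing designs** — exposure on day *d* vs mean `rm` of days *d*
  and *d+1* (the primary one-day-lag design), plus 7- and 14-day
  windows for heat-wave/cold-spell persistence.

Because the archival datasets such analyses are run on are typically not
redistributable, the package includes a first-class synthetic-data
generator (Helsinki-like climate, 1.0 → 1.6 M ageing population,
~29 expected deaths/day, configurable J-shaped excess with a sub-period
step change) whose ground truth drives the end-to-end test suite.

## Worked example

```python
import thermomort as tm
from thermomort import baseline, categories, exposure

cfg = tm.GeneratorConfig(rng_seed=1)          # 1971–2015 study defaults
weather, population, deaths, truth = tm.simulate_dataset(cfg)

popw = population.pivot(index="year", columns="age_group", values="population")
pop_daily = baseline.interpolate_population(
    popw["all"], start=deaths.index[0], end=deaths.index[-1])
rm = baseline.relative_mortality_pipeline(deaths["all"], pop_daily)

index = exposure.ThermalIndexSeries(
    weather["mean"].loc[rm.index[0]:rm.index[-1]], provenance="grid-average")
breaks = categories.percentile_breaks(index)
pairs = exposure.make_pairs(rm, index, window_days=2, lag_days=1)
table = categories.build_category_table(pairs, breaks)

print(f"study period: {rm.index[0].date()}..{rm.index[-1].date()} ({len(rm)} days)")
print(f"relative-mortality trend: {baseline.linear_trend(rm).slope:+.3f} %/decade")
```

which prints

```
study period: 1972-01-01..2014-12-31 (15706 days)
relative-mortality trend: -0.001 %/decade
```

— the 182-day smoothing edges and partial years are trimmed, and the
declining raw mortality (≈ −0.11 per 100,000 per decade in this run) has
been removed from `rm` entirely. The hot end of the category table
(`table.tail(3)`, rounded):

```
  label  range_low  range_high  n_days  mean_rm  ci_low  ci_high  trend stars  mean_a  mean_b stars_cmp
95–97.5       20.2        21.8     393      2.6     1.2      4.0   -1.3     *     5.1     0.8        **
97.5–99       21.8        23.4     235      4.6     3.0      6.3   -1.1           6.4     3.0         *
 99–100       23.4        29.0     158     10.4     8.2     12.5   -0.5          11.3     9.8
```

Reading the last row: on the 158 days above the 99th temperature
percentile (23.4–29.0 °C), mortality ran 10.4% (CI 8.2–12.5%) above its
seasonal baseline; the generator injected a heat effect that weakens at
the 1993 boundary, visible in the sub-period means (11.3% vs 9.8% here;
the Welch stars flag where the weakening is statistically significant).
Note that recovered excess systematically understates the injected
truth by ~2 percentage points in the top category — the Gaussian
baseline partially absorbs clustered heat-wave excess (see
`docs/methods.md`).

The same workflow runs from the shell:

```sh
thermomort run --seed 1 --outdir out/          # simulate + full analysis
thermomort simulate --config cfg.yaml --seed 2 --outdir data/
```

`run` writes `relative_mortality.csv`, `pairs.csv`,
`category_tables.csv`, `trends.csv`, `curves.csv`, a markdown `report.md`
and a `run_log.json` with every resolved default. To analyse real data
instead of simulating, point the config at `mortality.csv`,
`population.csv` and `weather.csv` (formats documented in
`thermomort.simulate`; PET is consumed as a precomputed column, it is
not computed here).

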
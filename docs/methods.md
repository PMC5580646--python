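# Methods

`thermomort` analyses how daily all-cause mortality responds to thermal
extremes over multi-decade periods during which population size, age
structure and baseline death rates all change. It follows the classic
biometeorological workflow: build a stationary *relative mortality*
series against a smoothed seasonal baseline, then summarize its
dependence on a thermal index (daily mean air temperature or a
precomputed thermal-comfort index such as PET) through percentile
categories and smooth exposure-response curves.

## Relative mortality (Koppe–Jendritzky baseline)

Daily death counts per age group are converted to rates per 100,000
using a daily population obtained by linear interpolation of annual
populations between mid-year (July 2) anchors; values outside the first
and last anchor are held flat. *Expected mortality* is the rate series
convolved with a symmetric truncated Gaussian kernel spanning 365 days.
*Relative mortality* is `rm(d) = 100 · (observed(d) − expected(d)) /
expected(d)`; it is dimensionless, stationary, and comparable across
decades regardless of population change.

**Edge policy.** The first and last 182 days have no complete window and
are dropped rather than renormalized; the analysis then restricts itself
to fully covered calendar years. Missing days are refused rather than
silently filled.

**Kernel width and σ.** The window is 365 days. The bandwidth σ controls
a trade-off that the implementation makes explicit:

* the baseline must *retain the annual cycle*: the filter's gain on the
  annual harmonic is `exp(−(2πσ/365.25)²/2)`, which is 0.967 at σ = 15 d
  but only 0.58 at σ = 61 d — a wide kernel flattens the seasonal cycle
  out of the baseline and leaks it into relative mortality (≈ −6%
  artificial summer deficit at σ = 61 d on synthetic data);
* the baseline must *remove day-to-day variability*: at σ = 15 d the
  white-noise variance transmitted is `Σw² ≈ 0.019`, a ~50-fold
  reduction.

The default is therefore **σ = 15 days**, exposed as configuration.

**Known limitation (baseline contamination).** Because the baseline is
computed from the observed series itself, mortality excess on clustered
extreme days is partially absorbed into the baseline: for 99th-percentile
heat days, which cluster into heat waves (persistent weather) inside one
summer, the kernel weight mass falling on a cluster is ~0.1–0.15, so
roughly 1.5–2.5 percentage points of a +15% injected excess disappear
into the baseline, and top-category mean relative mortality
systematically *understates* the true excess by that margin. No σ
removes this: small σ absorbs more of each heat-wave cluster, large σ
distorts the seasonal cycle (grid-measured minimum total bias ≈ −2.4% at
σ ≈ 15–20 d). Users comparing recovered excess against an external truth
should expect this attenuation; it is a property of the method, not of
the implementation.

**Trends.** Linear time trends are OLS of daily values on elapsed
decades (1 decade = 3652.5 days), with t-based 95% confidence intervals
and two-sided p-values. February 29 is an ordinary day; the convolution
runs over consecutive days, not day-of-year.

## Exposure pairing

The primary design pairs the thermal index on day *d* with the mean
relative mortality of days *d* and *d+1* (window 2, lag 1), so the
response includes the same-day and one-day-lagged signal. For heat-wave
and cold-spell persistence, 7- and 14-day designs average both exposure
and response over trailing windows labeled by the last day (a centered
variant is available by flag; trailing is the default because it is the
natural causal orientation). Daily index values may come from station
sub-daily data (unweighted daily mean, days with fewer than 6 of 8
three-hourly slots marked missing) or as unweighted spatial averages of
grid-cell series.

## Percentile categories

Breakpoints are empirical quantiles (linear interpolation of order
statistics, configurable) of the index over the *whole* study period at
levels 1, 2.5, 5, 10, 25, 50, 75, 90, 95, 97.5 and 99%, defining 12
categories; the same breakpoints are reused for sub-period analyses.
Intervals are right-closed, `(b_{k−1}, b_k]`, so a value equal to a
breakpoint goes to the lower category; values beyond the observed range
are still classified (bottom/top category). Per category and age group
(`all`, `<65`, `65–74`, `≥75`, and `≥65` as the union of the last two)
the table reports the mean response with a 95% t-interval, the OLS trend
in %/decade with stars at 0.05/0.01/0.001, sub-period means (defaults
1972–1992 vs 1994–2014, the boundary year excluded), a Welch two-sample
t-test (Welch–Satterthwaite df), and Shapiro–Wilk normality p-values per
sub-period (subsampled to 5,000 points when larger). t-intervals ignore
day-to-day autocorrelation of relative mortality, matching common
practice; a moving-block bootstrap CI is available for sensitivity. No
multiple-testing correction is applied, and the report footer says so.

## Smooth exposure-response curves

Relative mortality is regressed on the index with a cubic B-spline basis
(default dimension 10, equally spaced interior knots over the observed
exposure range) and a curvature penalty `λ∫f″²`; λ is selected by GCV
(coarse log-grid search refined by bounded scalar minimization). The
penalty null space is exactly the linear functions, so λ → ∞ recovers
the OLS line; `λ = inf` is computed exactly through that limit.
Pointwise 95% bands use the Bayesian posterior covariance
`σ̂²(BᵀB + λS)⁻¹`. The curvature penalty matrix is evaluated exactly by
two-point Gauss–Legendre quadrature per inter-knot interval (the
integrand is piecewise quadratic for cubic splines). Curves are fitted
for the whole period and each sub-period; evaluation between grid nodes
is linear interpolation with no extrapolation. With basis dimension 10
the bands' average pointwise coverage of a smooth J-shaped truth
measures ≈ 91–95% in simulation — slightly below nominal where the curve
bends faster than the knot spacing can follow; raising the basis
dimension restores coverage at the cost of rougher fits.

## Synthetic-data generator

The archival mortality and weather records this kind of analysis runs
on are typically not redistributable, so the generator produces series
with the same statistical structure,
plus the ground truth needed for recovery testing:

* **Weather.** Daily mean temperature = annual mean 5 °C + seasonal
  cosine of amplitude 12 °C peaking mid-July + linear warming
  0.4 °C/decade + stationary AR(1) anomalies (φ = 0.8, innovation sd
  2.4 °C, marginal sd 4 °C). These values describe a Helsinki-like
  climate; the AR(1) persistence makes extreme days cluster into
  realistic heat waves and cold spells. Multiple grid cells are
  exchangeable noise replicates around the shared signal (no spatial
  correlation structure); 3-hourly output adds a mean-zero diurnal
  cosine so the daily mean is preserved exactly.
* **Population.** Linear growth 1.0 → 1.6 million with age-group shares
  shifting linearly so the ≥65 share grows from 9.1% to 16.5%.
* **Deaths.** Poisson counts per age group around
  `pop/1e5 · rate · (1 + seasonal) · (1 + g(T_lagged)/100)`, with
  winter-peaking seasonal amplitude 0.15 (mid-January peak), group rates
  declining linearly so that the all-ages rate averages ≈ 2.2/100k/day
  and declines ≈ −0.12/decade while the ≥75 rate averages ≈ 24/100k/day
  (≈ 29 expected deaths/day overall). Because the share interpolation is
  linear, the implied ≥75 rate decline is somewhat steeper than in real
  demography — a deliberate simplification. An optional overdispersion
  factor (gamma-mixed Poisson) exists but defaults off, since the
  analysis nowhere models overdispersion.
* **Excess curve.** Piecewise response `g(T)`: hot branch
  `step + slope·(T − threshold)` above a threshold (defaults 17 °C,
  2.7 %/°C halving to 1.35 %/°C at the 1993 boundary — a step change,
  the simplest structure a two-sample test can detect), cold branch
  0.3 %/°C below −10 °C, per-age-group scale factors (0.8 / 1.0 / 1.3)
  making the elderly most heat-sensitive. The effect acts on temperature
  at a configurable lag (default 0). The truth object stores the
  noiseless expected deaths, the effect-free baseline and the realized
  `g` series, all bit-reproducible from config + seed.

All randomness derives from one seed through named
`numpy.random.SeedSequence` streams (per grid cell, per age group), so
outputs are bit-identical across reruns and independent of call order.

**What passing tests do and do not show.** The generator reproduces the
first-order structure the analysis relies on — seasonality, trend,
counting noise, clustered extremes, a J-shaped response — but not
influenza epidemics, harvesting dynamics, spatially correlated weather,
cause-of-death structure, or demographic shocks. Recovery of injected
effects on these data therefore validates the *machinery*, not the
epidemiological interpretation of any real-data run.

## Problem sizes used in checks

Simulation-based checks run the full 45-year configuration (16,436 days,
analysed 1972–2014) over 50–100 seeds for distributional claims, and
shorter 8–10-year configurations for structural and determinism checks.
Curve-fidelity checks use n = 15,000 exposure-response pairs per seed
with noise sd 13% (matching the daily relative-mortality noise scale at
~29 deaths/day).
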
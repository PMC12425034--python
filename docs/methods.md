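# Methods

## Study design and estimand

The package implements a single-step, pooled time-stratified case-crossover
analysis of daily temperature and daily road-traffic death counts across
many cities.  A two-stage meta-analytic design (city-specific fits pooled
by meta-regression) is deliberately not offered: city-level models do not
converge when a city records only a handful of road deaths, which is the
typical regime.  Instead all cities enter one conditional quasi-Poisson
model whose stratum term is city x year x month x day-of-week.  Each case
day is thereby matched 1:3 or 1:4 to the other same-weekday days of the
same city-month, which removes seasonality, secular trends, day-of-week
rhythm and every city-constant confounder by design.  The estimand is the
cumulative (over lags) relative risk of death at a given temperature
percentile versus the minimum-mortality temperature percentile (MMTP), plus
the excess death fraction (EDF) for days at or above the 95th percentile.

## Exposure standardization

Daily mean temperature (degrees C) is converted within each city to a
percentile over all available days, using midpoint ranks:
`p = 100 (r - 0.5) / n` with average ranks for ties.  Midpoint ranks keep
percentiles strictly inside (0, 100) — no atom sits on a spline boundary
knot — and map a constant series to 50.  The transform is idempotent and
invariant to any strictly monotone transformation of temperature.  Working
in percentiles guarantees complete overlap of exposure ranges across cities
with very different climates; an absolute (degrees C) exposure scale is
retained as an option for sensitivity analyses, with boundary knots at the
pooled data range.

## Cross-basis

The exposure-response dimension is a natural cubic spline with internal
knots at the 10th, 75th and 90th percentiles and boundary knots at 0
and 100 (4 columns; linear beyond the boundary, zero second derivative
there).  The basis is implemented in the truncated-power representation
with the natural constraints applied in closed form; it spans the same
function space as B-spline formulations, which is all that matters for the
fit, and is verified in tests by finite-difference boundary checks and by
exact reproduction of linear functions.  Six alternative knot sets commonly
used in heat-mortality work are exposed as presets for sensitivity
analyses.

The lag dimension covers lags 0-2 days — road deaths follow their
precipitating incident within about two days, a much shorter horizon than
other heat-mortality pathways — with one indicator column per lag
(unconstrained lag strata).  The indicator lag basis is a deliberate
modelling choice and is kept pluggable in the spec object.
With it, the cross-basis has 4 x 3 = 12 columns, and a modifier
interaction adds exactly 12 parameters, matching the 12-df likelihood
ratio tests the analysis reports.  Days without a complete lag history
(the first two of each series) are dropped before strata construction
rather than padded, so stratum sizes reflect usable days only.

## Estimation

Conditioning on each stratum's total count eliminates the stratum
intercepts exactly: within a stratum with total `N_s` the likelihood is
multinomial over its days with probabilities
`exp(x_i beta) / sum_j exp(x_j beta)`.  The implementation maximizes this
concave objective by Newton-Raphson with step-halving, converging when the
relative deviance change falls below 1e-9 (cap: 100 iterations; a
per-stratum max is subtracted before exponentiation for stability).
Strata with zero total count contribute nothing and are dropped — a test
asserts dropping them is exactly a no-op.  The covariance is the inverse
conditional information scaled by the Pearson dispersion
`phi = X^2_P / (n - p - S)` with `S` the number of used strata, mirroring
an unconditional Poisson fit with stratum dummies (agreement with such a
fit is verified to 1e-12 on small panels, and against brute-force
maximization of the explicit conditional likelihood on toy problems).

Nested models are compared by the unscaled Poisson deviance difference
against a chi-square reference — the convention behind reported chi-square
LR statistics — computed on a single dataset (for imputed data, the
across-imputation median series).  A dispersion-scaled F variant is
provided behind a separate function for users who prefer it.

## Cause-of-death redistribution

Around 11% of external-cause death records carry ill-defined ICD-10 codes.
A multinomial logit (statsmodels MNLogit) is fitted on well-defined records
with outcome {pedestrian, bicycle, motorcycle, motor vehicle, non-road}
and predictors five-year age band, sex, country (categorical; first level
reference) and year (continuous, centred — the parsimonious default where
no functional form is prescribed).  Each ill-defined record then receives
`m` independent categorical draws from its predicted probabilities
(default `m` = 100).  One RNG substream per imputation index is derived
from the master seed, so increasing `m` never perturbs earlier
imputations.  Completed records aggregate to daily series in which the
overall count is the sum of the four road modes and non-road records are
dropped.  The across-imputation median series uses the lower central order
statistic for even `m` so counts stay integral for the Poisson stages;
because cellwise medians are not additive, stratum medians may exceed the
overall median on a given day, and the series container relaxes its
stratum-sum bound for such summaries.  Handling of the residual "other
road user" ICD range is out of the default category set; deaths of unknown
sex or age are kept in the overall count and excluded from subgroup
columns.

Model fits run once per completed dataset and are pooled with Rubin's
rules: mean coefficients; total covariance `T = W + (1 + 1/m) B` with `W`
the mean within-imputation covariance and `B` the between-imputation
sample covariance (n-1 denominator).  `T - W` is positive semi-definite by
construction, asserted by an eigenvalue test.

## Curves, MMTP and EDF

The MMTP is the argmin of the cumulative log-RR over integer percentiles
1..99 (reference-invariant; ties to the smallest percentile; a finer grid
changes nothing material for a 4-df spline).  RR curves are evaluated on
the same grid, centred at the MMTP — and, for subgroup, cluster and
modifier analyses, at the MMTP of the overall main-effects analysis, so
all curves share one reference.  Pointwise 95% intervals use the delta
method on the contrast with the pooled covariance.

The EDF takes the backward attributable-fraction perspective: day `t`
contributes `n_t (1 - exp(-eta_t))` attributable deaths, where `eta_t` is
the cumulative log-RR of the day's own lagged exposure history versus the
MMTP; the EDF divides the sum over days at or above the threshold
percentile (default 95) by all deaths.  The forward variant is not
implemented.  The empirical 95% interval re-evaluates the EDF under
`n_sim` = 1000 multivariate-normal coefficient draws from the pooled mean
and total covariance, conditioning on that pooled summary (the imputation
stage is not re-sampled).  The EDF is invariant to rescaling all counts.

## Clustering and effect modification

Cities are profiled by five empirical quantiles of daily temperature
(1st, 10th, 75th, 90th, 99th; linear-interpolation estimator — the extreme
pair attenuates outlier influence relative to min/max).  Profiles are
z-scored coordinate-wise across cities (sample SD) and clustered by
Ward-linkage agglomerative clustering, cut at `k` = 6 by default;
descriptive cluster labels are user-supplied, not computed.  Cluster- and
subgroup-specific estimates re-run the same pipeline on city subsets or
outcome columns.

City-level effect modification appends `z x` (modifier times each
cross-basis column) to the design; the modifier main effect is absorbed by
the city-nested strata and is not added.  Marginal curves at the 10th and
90th percentiles of the modifier's across-city distribution use
`beta_main + z beta_int` with delta-method covariance `[I, zI] T [I, zI]'`.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, at the scale of
a large Latin-American city panel, with every stage deterministic given
(seed, config) via independent substreams:

* **Climate**: per-city sinusoidal seasonality,
  `T_ct = mean_c + A_c sin(2 pi doy / 365.25 + phi_c) + N(0, sigma_c)`,
  with city means drawn around 21.2 degrees C (SD 4), amplitudes 2-8
  degrees and daily noise 1-3 degrees — matching the panel-level mean and
  spread of daily temperatures the analysis targets.
* **Counts**: Poisson (negative binomial when overdispersion > 1) with
  log-mean = log(baseline) + month and day-of-week multipliers + the
  lag-weighted true cumulative log-RR curve.  The default baseline is
  0.3375 deaths/city-day (33.75 per 100 days).  The truth curve is
  piecewise linear in percentile space between user-set (percentile, RR)
  anchors, flat at zero below its reference percentile, linearly extended
  above the last anchor; lag weights default to (0.6, 0.3, 0.1) — any
  simplex point works for recovery, as the indicator lag basis estimates
  each lag freely.
* **Attributes**: each day's count is partitioned multinomially into mode,
  sex and age-group columns (shares normalize the emulated panel's
  per-mode/sex/age averages, so strata sum exactly to the overall count);
  records expand those tallies to one row per death, add an independent
  non-road record stream, and mask an 11% fraction of causes as
  ill-defined while retaining the truth in a hidden column for recovery
  tests.  Mode-specific truth curves can be planted by generating modes as
  independent Poisson streams.

The generator deliberately omits spatial correlation between cities,
climate-change trends, temperature measurement error and within-city
heterogeneity of baseline rates.  Passing recovery tests therefore shows
the estimator chain is correct and calibrated under the assumed data
generating process, not that real panels satisfy those assumptions.

## Recovery experiments and problem sizes

A single panel at the emulated scale (40 cities x 1095 days, 0.3375
deaths/city-day, about 15,000 deaths) yields Monte-Carlo standard errors
of roughly 0.08-0.10 on the RR scale at the 95th percentile for the
overall outcome, and roughly 0.3 at the 99th percentile for the
motorcyclist outcome (about 2,700 deaths) — far larger than the margins at
which recovery is asserted.  Recovery is therefore measured on replicated
panels: the pooled estimate is the exponential of the unweighted mean of
replicate log-RRs, with 50 replicates for the overall outcome and 100 for
the motorcyclist outcome.  Pooling is unweighted because inverse-variance
weights correlate with the estimates in Poisson models and bias the pool
downward.  Subgroup curves are centred at each replicate's overall
main-effects MMTP, as in the analysis proper.  The null-calibration
experiment (type-I error of the 12-df interaction LR test) uses 500
replicates of an 8-city x 2-year panel at 1 death/city-day.

## Known limitations

* The conditional fit assumes counts are independent across days given the
  stratum total; infectious-disease-style serial dependence would violate
  this.
* The quasi-Poisson LR test uses unscaled deviance; under strong
  overdispersion the F variant is preferable.
* Perfect-separation detection in the redistribution model is heuristic
  (it names a candidate predictor by zero-cell crosstabs).
* Ward clustering of standardized profiles is deterministic but
  tie-breaking among identical profiles follows input order.
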
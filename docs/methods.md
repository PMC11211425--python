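# Methods

This note documents the statistical model, the conventions the package fixes
where several readings are defensible, the synthetic data-generating process,
and the numerical choices. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Event definitions and classification

A candidate definition is a triple (kind, percentile, minimum duration).
Heat waves use the percentile grid {75.0, 77.5, 80, 82.5, 85, 87.5, 90,
92.5, 95} of the community's **hot-season** (May–September) daily values
pooled over all study years; cold spells use {25.0, 22.5, 20, 17.5, 15,
12.5, 10, 7.5, 5.0} of the **cold-season** (November–March) values; both
grids use durations ≥2 and ≥3 days, giving 18 definitions per kind.
Quantiles are computed with the linear-interpolation rule (the common
default of mainstream statistical software). Thresholds are community-
specific ("relative" thresholds), computed once per community from all
season-restricted days; a per-year variant is possible but is not the
default. A day is flagged when it belongs to a maximal run of at least the
minimum duration of qualifying days; missing temperature days break runs and
are excluded from threshold computation. Cold-season blocks run from
1 November through 31 March of the following calendar year, and runs may
cross 31 December; runs never bridge the seasonal gap (April, October) or a
gap in the data.

**Day/night pairing.** Daytime events are detected on the daily maximum
temperature, nighttime events on the daily minimum. The daily minimum
recorded on calendar day *t* occurs in the early morning — the night
*preceding* that day's afternoon maximum — so the nighttime paired with
daytime *t* is `tmin[t]`, and the per-day label is:

| day flag | night flag | label |
|---|---|---|
| 1 | 1 | compound |
| 1 | 0 | daytime_only |
| 0 | 1 | nighttime_only |
| 0 | 0 | none |

This makes "preceding nighttime plus following daytime" a single calendar
date and guarantees exactly one label per day.

**Humidity stratification.** Event days are split at a single national
cutoff: the median relative humidity pooled over all community-days in the
analysis seasons (union of hot and cold seasons by default; a single-season
pooling is available via the `season` argument). Ties at the cutoff go to
the *high* stratum. Event days with missing humidity receive a `missing`
stratum and are logged, so low + high always partitions the event days with
observed humidity — an invariant the tests assert.

## First-stage model

For one community, season and mortality group, daily counts are modelled as
quasi-Poisson (log link, Var = φ·mean) with linear predictor

    intercept
  + natural cubic spline of day-of-season (4 df; day 1 = 1 May or 1 Nov)
  + year indicators (calendar year in the hot season; season-year in the
    cold season, so a season spanning the New Year is one unit)
  + day-of-week dummies (6) + public-holiday dummy
  + cross-basis of relative humidity (5 df variable x 4 df lag, lag 0-10)
  + cross-basis of air pressure (same specification)
  + event-type regressors

The default confounder set contains humidity and pressure cross-bases; an
optional mean-temperature cross-basis and a 3-df same-day PM2.5 spline
(restricted to days with data) are available behind configuration flags.
Temperature itself enters primarily through the event definitions; adding a
temperature main effect alongside the event dummies is deliberately not the
default because the two are strongly collinear by construction.

**Cross-basis.** Row *t*, column *(i, j)* of a cross-basis is
Σ_{l=0..L} B_var,i(x_{t−l}) · B_lag,j(l). Variable-dimension knots sit at
equally spaced quantiles of the observed series with boundary knots at its
range; lag-dimension knots are equally spaced on the log(lag+1) scale with
boundary knots at 0 and L, and the lag basis carries an intercept column so
that lag-constant effects are inside the model space. A saturated
(indicator) lag basis and a purely linear variable basis are available; with
those the cross-basis model reproduces the unconstrained distributed-lag
model exactly, which the tests verify to 1e-8. The spline basis is the
truncated-power natural cubic construction, evaluated on an affinely
rescaled variable for conditioning; it is linear beyond the boundary knots
(checked by finite differences) and, together with an intercept, spans all
linear functions.

**Event regressors.** Three per model (daytime-only, nighttime-only,
compound), or six when humidity-stratified. Two lag treatments: a single
lag ℓ (the flag shifted ℓ days) or a moving average over lags 0..L, under
which exp(β) is the rate ratio for a window fully covered by the event.
Default reporting windows: cumulative lag 0–1 for heat waves and lag 0–14
for cold spells, matching the typical acute heat response and the delayed,
persistent cold response. Rows with incomplete lag history — the first
max(L, max covariate lag) days of each season block — are dropped from the
likelihood, not imputed. An event regressor that is identically zero on the
retained rows (no events of that type that season) is dropped as aliased and
the effect is reported missing rather than zero.

**Fitting.** IRLS on the Poisson likelihood: start at intercept
log(mean(y)+0.5) and zero elsewhere; step-halving enforces a non-increasing
deviance; convergence requires the maximum absolute score below
1e-8·(1+Σy) together with a relative deviance change below 1e-10; at most
100 iterations. Aliased columns are detected by pivoted QR and dropped with
a logged warning. φ is the Pearson χ²/(n−k), floored at 1e-8 with a warning
for degenerate inputs; the coefficient covariance is φ·(XᵀWX)⁻¹, so
quasi-Poisson standard errors are exactly √φ times the Poisson ones.

**Q-AIC.** The definition competition is scored by QAIC = −2ℓ + 2φk, the
convention of the time-series air-pollution literature; the alternative
−2ℓ/φ + 2k is available (`variant="scaled"`). Only within-dataset
comparisons are ever made, so the variant does not affect which definition
wins a given competition in practice. Per province, each candidate is fitted
for every community and group; the minimum mean Q-AIC wins; exact ties break
toward the less severe percentile, then the shorter duration; candidates
with zero events everywhere are excluded. A fixed-definition mode (90th/10th
percentile, ≥2 days) bypasses selection for sensitivity analyses.

## Second stage

Community log relative risks b_i with variances v_i are pooled under
b_i ~ N(μ, v_i + τ²). τ² maximizes the restricted likelihood, found by
bounded scalar minimization on [0, max(10·var(b), 10·max(v))] with
xatol 1e-12, with the τ²=0 boundary taken whenever it does at least as well —
the tests verify the optimum against a step-1e-4 grid search within 1e-8.
Heterogeneity is reported as Cochran's Q (fixed-effect weights), its
chi-square p-value, and I² = max(0, (Q−df)/Q)·100. Subgroup contrasts use
the normal Z-test on the difference of pooled log effects. No
Knapp–Hartung small-sample adjustment is applied by default (none is implied
by the two-stage convention followed here); the Wald normal quantile
1.959964 is used throughout.

Meta-regression is univariable (intercept + one predictor) with REML-profiled
residual τ²; the slope is reported per interquartile range on the percentage
scale, 100·(exp(slope·IQR)−1), with the Wald interval transformed the same
way. The "share of total variance that is between-study" is
τ²_res/(τ²_res + s²)·100 with the Higgins–Thompson typical within-study
variance s² = (k−1)Σw/((Σw)²−Σw²), w = 1/v — one of several conventions in
use; it is fixed and documented here because the quantity has no unique
definition. Communities with missing or non-converged first-stage effects
are excluded listwise per analysis, with counts logged.

## Synthetic data generator

The generator emulates a national mortality-surveillance panel; its defaults
are set to the descriptive magnitudes of a 161-community Chinese panel
(2007–2013): annual-mean temperature 13.4 °C with seasonal amplitude 11 °C
peaking at day 197, diurnal range 9.8 °C (lognormal day-to-day spread 0.2),
AR(1) temperature noise (coefficient 0.7, marginal SD 2 °C), relative
humidity mean 65.8% / SD 18.5% (AR(1), clipped to [0,100]), air pressure
950 ± 8.5 hPa, and 7.4 deaths per community-day with winter-peaking
seasonality of log-amplitude 0.15 and dispersion 1.3.

Counts are negative binomial with per-day size μ/(φ−1), giving exactly
Var = φ·μ (Poisson at φ=1), so the first-stage dispersion estimate recovers
the generator's φ — a moment identity the tests check within 10% at n ≥
5,000 days. Event effects are injected through the labels produced by the
package's own classifier on the simulated weather (default injection
definitions: heat 92.5th percentile ≥3 days, cold 7.5th ≥3 days), so labels
and effects are consistent by construction; per-community true log-RRs are
drawn N(β, τ²) and returned in a ground-truth table. Lag weights distribute
an injected effect over lags (default: all at lag 0). Randomness uses one
root `SeedSequence`; per-community streams are spawned children, so adding a
community leaves existing panels bit-identical.

What the generator does **not** emulate: spatial correlation of weather
across communities (communities are independent — a deliberate
simplification), climate-zone structure, reporting artifacts, demographic
drift, or any direct smooth temperature–mortality dose-response outside the
event indicators. Passing recovery and calibration tests therefore
demonstrates the correctness of the estimation machinery under the stated
model, not robustness to every feature of real surveillance data.

## Problem sizes used in the test suite and acceptance script

Replicated calibration checks use 20 communities × 5 years per replicate
(500 replicates for parameter recovery and null calibration), 2-community
provinces × 5 years for the 100-replicate definition-selection study, and
200 random 1,000-day series for the brute-force classification oracle —
sizes chosen so the whole suite runs on a laptop-class single core while
keeping Monte-Carlo error well inside the asserted tolerance bands.
`scripts/acceptance.py` simulates 24 communities × 7 years (τ = 0.03) with
injected effects on all six kind × event-type combinations; at that scale
the pooled percentage changes carry Monte-Carlo uncertainty of roughly ±3
percentage points, which the script surfaces as explicit `recovery_error`
entries rather than hiding.

## Known limitations

- The estimand of the moving-average parameterization (fully covered
  window) differs from a distributed-lag cumulative effect when true effects
  decay within the window; profiles over single lags 0–21 are provided to
  inspect the decay.
- Pearson-based dispersion and Wald intervals can be optimistic in
  communities with very few event days; such communities legitimately
  inflate τ̂² in the pooling stage.
- Q-AIC averages are comparable only within a fixed dataset; the selection
  stage never compares values across provinces.
- The REML search is scalar; multivariable meta-regression (several
  modifiers at once) is out of scope.
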
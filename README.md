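# thermex

Two-stage statistical pipeline for estimating the mortality risks of
daytime-only, nighttime-only and **compound daytime–nighttime** temperature
extremes (heat waves and cold spells) from multi-community daily panels of
weather and death counts.

## The problem

Heat waves and cold spells are usually detected on a single daily temperature
metric, which conflates events confined to the day, events confined to the
night, and sustained events spanning both. The distinction matters: a night
that offers no relief from heat disrupts recovery and sleep, so compound
day–night events are expected to be more harmful than either one alone.
This package implements the full analysis chain needed to quantify that
difference from surveillance-style data:

1. **Event classification** (`thermex.events`). A grid of 18 heat-wave
   definitions (percentile thresholds 75.0–95.0 of the community's hot-season
   daily maxima, durations ≥2 and ≥3 days) and 18 mirror-image cold-spell
   definitions (percentiles 25.0–5.0 of cold-season daily minima). Daytime
   events are runs in the daily maximum, nighttime events runs in the daily
   minimum; because the daily minimum is recorded in the early morning of the
   same calendar day as the following maximum, day *t* is labelled
   `compound` when both flags fire on *t*, `daytime_only`/`nighttime_only`
   when exactly one fires, else `none`. Event days are optionally split at
   the national median relative humidity.
2. **Community-level regression** (`thermex.splines`, `thermex.glm`,
   `thermex.firststage`). For each community, season (hot: May–September;
   cold: November–March, crossing the New Year) and mortality group, daily
   counts Y_t are modelled as overdispersed Poisson with

   log E[Y_t] = α + ns(day-of-season, 4) + year + DOW + holiday
              + CB(RH; 5×4, lag 10) + CB(P; 5×4, lag 10) + β·E_t

   where `ns` is a natural cubic spline, `CB` a DLNM cross-basis (natural
   cubic splines in the variable and the lag dimension), and E_t the
   event-type regressor — a single-lag indicator or a moving average over
   lags 0..L, so exp(β) is the rate ratio of a fully exposed window. Fitting
   is by IRLS; dispersion φ is the Pearson χ²/(n−k); candidate event
   definitions are ranked per province by the mean Q-AIC = −2ℓ + 2φk.
3. **Pooling** (`thermex.meta`). Community log relative risks are combined
   by REML random-effects meta-analysis (between-community variance τ²,
   Cochran's Q, I²), subgroups are compared with Z-tests, and community-level
   modifiers are assessed by per-IQR univariable meta-regression, reporting
   100·(exp(slope·IQR)−1) and the share of total variance that is
   between-community.
4. **Synthetic panels** (`thermex.synthetic`). Because real mortality
   surveillance data are access-restricted, the package ships a generator of
   multi-community panels — sinusoidal seasonal weather with AR(1) noise and
   a positive diurnal range, negative-binomial death counts with
   Var = φ·mean and injected event effects drawn around known values — so
   every stage can be validated against ground truth.

Effects are reported as percentage change 100·(exp(β)−1) with 95% Wald
intervals, by default cumulatively over lags 0–1 for heat waves and 0–14 for
cold spells.

## Worked example

Simulate a 10-community study (compound heat-wave log-RR 0.0849 injected,
i.e. +8.9%, with between-community SD 0.02) and fit one community:

```
thermex simulate --out-dir study --n-communities 10 --years 2007-2013 --seed 1
thermex fit --panel study/panels/c005.csv --kind heat_wave --percentile 92.5 --duration 3
```

The `fit` command prints the community-level effects of one definition:

```
dispersion: 1.318  converged: True
   daytime_only (lag 0-1 MA):   9.54% (95%CI -16.96, 44.50)  events=15
 nighttime_only (lag 0-1 MA):  -2.54% (95%CI -29.82, 35.33)  events=11
       compound (lag 0-1 MA):  21.80% (95%CI 0.18, 48.09)  events=24
```

With ~7 deaths/day and only ~20 event days per community-study, single
communities are noisy (intervals span tens of percent); the signal emerges
in the second stage. The full two-stage run

```
thermex run-all --config study/config.yml --seed 1
```

writes `community_effects.csv`, `selected_definitions.csv` (with the Q-AIC
grid per province), `pooled_effects.csv`, `contrasts.csv`, `metareg.csv`
and `summary.json`. The pooled table from this 10-community run:

```
      kind     event_type   pct  pct_lo  pct_hi  tau2     Q    I2  k
cold_spell       compound 30.88    2.94   66.41  0.01 10.16 21.29  9
cold_spell   daytime_only 10.47  -12.43   39.36  0.05 14.02 35.79 10
cold_spell nighttime_only 19.10    0.56   41.05  0.00  9.13  1.45 10
 heat_wave       compound -1.47   -6.38    3.70  0.00  6.88  0.00 10
 heat_wave   daytime_only  3.16   -3.37   10.12  0.00 10.21 11.86 10
 heat_wave nighttime_only -8.35  -14.94   -1.24  0.00  9.98  9.84 10
```

The compound cold spell comes out clearly elevated; at only k = 10
communities the heat-wave rows are still dominated by sampling noise (and
one province's Q-AIC selection picked a definition other than the injecting
one, which attenuates its estimates toward zero). The calibration of the
whole chain — bias under 10% of the injected effect and 93–97% CI coverage
— is established by the 500-replicate simulations in
`tests/test_acceptance.py`, not by any single run.

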
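# stepnof1

Design, simulation and analysis for **factorial N-of-1 randomized trials
of physical-activity interventions** with daily step counts and
ecological momentary assessment (EMA).

In an N-of-1 RCT each participant is their own control: intervention
conditions are randomized to time periods *within* a person, and the
person-day time series is the unit of analysis.  This package implements
the full pipeline for a 40-day 2×2 factorial design crossing two
app-delivered components — digitalized motivational interviewing (dMI)
and heart-rate-variability biofeedback — against daily step counts, with
morning/evening EMA measures of self-efficacy, motivation, perceived
barriers and pain:

- **`stepnof1.design`** — randomized 40-day schedules: twelve 3-day
  periods block-randomized over the four conditions, wash-out days after
  intervention periods, extra control days after periods 4 and 8, and a
  2-day lead-out (7 availability windows per component, 11 control days,
  9 wash-out days).
- **`stepnof1.cohort`** — a calibrated synthetic-cohort generator
  (participant data of the motivating study are not deposited):
  steps with person-level heterogeneity (ICC 0.571), a random time
  slope, weekday periodicity, AR(1) residuals, 1–9 EMA scales with a
  self-efficacy–motivation correlation of 0.597, ordinal pain, realistic
  missingness and engagement patterns.
- **`stepnof1.nof1`** — per-participant dynamic regression: screens for
  time trends, weekday cycles and autocorrelation lags, then regresses
  steps on intervention availability (or one EMA predictor) with
  barriers/pain controls.
- **`stepnof1.mlm`** — the aggregated six-model multilevel ladder with
  within/between-person centering and gap-aware AR(1) residuals.  For
  participant *i*:

      y_i ~ N( X_i β,  Z_i G Z_iᵀ + σ² R_i ),   R_i[j,k] = ρ^|t_j − t_k|

  with G the random intercept/slope covariance (τ00, τ11, τ01).  Models
  are compared by ML deviance chi-square tests; inference uses a REML
  refit with a Kackar–Harville covariance correction.
- **`stepnof1.mcar`** — Little's test of missing-completely-at-random
  via EM for the multivariate normal.
- **`stepnof1.evaluation`** — Monte-Carlo parameter recovery, type-I
  error and power experiments for the whole design.

## Worked example

```python
import stepnof1 as s

cfg = s.default_config()                    # calibrated 15 x 40-day cohort
study = s.simulate_study(cfg, seed=7)       # schedules + data + missingness
ladder = s.run_ladder(study, mode="predictor:self_efficacy")
print(ladder.table().round(1).to_string(index=False))
fe = ladder.final.fixed["se_morning_within"]
print(f"ICC (null model): {ladder.icc:.3f}")
print(f"within-person self-efficacy: B={fe.B:.0f} (SE {fe.SE:.0f}; "
      f"95% CI {fe.ci_low:.0f} to {fe.ci_high:.0f}), P={fe.P:.2g}")
```

prints

```
                                                      model  n_params  minus2ll  chi2   df   P    BIC
                             1: fixed and random intercepts         3    8364.0   NaN  NaN NaN 8382.3
                                    2: model 1 + fixed time         4    8343.4  20.7  1.0 0.0 8367.7
                              3: model 2 + random time (UN)         6    8342.2   1.2  2.0 0.6 8378.7
4: model 3 + day of week + barriers + pain (within/between)        16    8273.2  69.0 10.0 0.0 8370.5
        5: model 4 + se_morning_within + se_morning_between        18    8206.9  66.3  2.0 0.0 8316.4
                  6: model 5 + AR1 residual autocorrelation        19    8205.5   1.3  1.0 0.2 8321.1
ICC (null model): 0.534
within-person self-efficacy: B=487 (SE 59; 95% CI 370 to 603), P=2.4e-15
```

Reading this: a bit over half the step variance is stable between-person
differences (ICC 0.53 in this replicate; the generator's target is
0.571), adding the within/between self-efficacy pair clearly improves
fit (model 5, χ²₂ = 66.3), and on days a participant's morning
self-efficacy is one point above their own average they take ≈487 more
steps (the generating value is 462).  Model 6 shows little residual
day-to-day autocorrelation once covariates are in — the same shape of
conclusion the aggregated analysis of such a trial produces.

The same pipeline is scriptable from the shell:

```sh
stepnof1 simulate --seed 11 --out cohort.csv
stepnof1 analyze-mlm  --data cohort.csv --mode se --out results/
stepnof1 analyze-nof1 --data cohort.csv --mode intervention --out results/
stepnof1 mcar-test    --data cohort.csv
stepnof1 evaluate recovery --reps 200 --seed 1 --out results/
```

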
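# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `stepnof1`.

## The trial design

Each participant runs their own 40-day randomized experiment crossing
two app-delivered intervention components — digitalized motivational
interviewing (dMI) and HRV-biofeedback (BF) — in a 2×2 factorial:
twelve 3-day active periods, each block-randomized to one of four
conditions (both, dMI only, BF only, control).  Randomization is
*repeated block randomization*: the 12 periods split into three
consecutive blocks of four, and each block receives an independent
uniform permutation of the four conditions, so every condition occupies
exactly three periods.  Inside an active period the condition's
components are available on days 1–2; day 3 is a wash-out day after any
intervention period (components withheld, eliminating carryover) and a
third control day after a control period.  Single extra control days
follow periods 4 and 8, and the trial closes with a 2-day lead-out in
which both components are available.  The arithmetic consequences used
throughout the tests: 40 days, 7 dMI windows, 7 BF windows, 11 control
days, 9 wash-out days, 2 lead-out days; with 15 participants, 600
person-days in total and 465 outside wash-out.

One reading note: a literal reading of the design prose would also give
control periods a wash-out day, but that produces 420 rather than 465
non-wash-out person-days and 12 rather than 11 control days; the day-3
labeling above is the only one consistent with the design counts, and
the package follows it.

## The synthetic cohort

No participant-level data are deposited, so all analyses run against a
generator that emulates the study's data structure.  For participant
*i* on day *t*:

    steps_it = (b0 + u0i) + (b1 + u1i)·t + weekday(t)
               + bDMI·dmi_it + bBF·bf_it
               + bw·(x_it − x̄_i) + bb·(x̄_i − x̄)          (driver channel)
               + analogous barriers and pain terms
               + e_it,       e_i ~ stationary AR(1), Var e = σ², lag-1 ρ

with (u0i, u1i) bivariate normal (τ00, τ11, τ01), steps floored at 0 and
rounded (accelerometers report non-negative integer counts; the
calibrated configuration makes the floor bind on ≈0.5% of days).  EMA
items are latent standard normals discretized into nine
equal-probability bins (1–9 visual-analog scales) with a person-level
variance share (0.32 for EMA items, 0.45 for pain) producing trait-like
stability; pain is a 0–2 ordinal with marginal probabilities
(0.85, 0.11, 0.04).  Self-efficacy and motivation latents are correlated
so that the *observed* scales correlate at r = 0.597 (the latent
correlation is inflated by the 9-bin discretization attenuation factor
0.9312).  Only one of the two (the `driver`) causally moves steps — two
collinear causes would be unidentifiable, which is also why the analyses
model them separately.  Between-person channels are centered at the
cohort mean of person means, the same reference the analysis models use,
so the configured intercept keeps its meaning in every generated cohort.

Default calibration (steps, steps/day, steps per scale point):
b0 = 11137, b1 = −23, Monday +2303 and Wednesday +1609 versus Sunday
(other days 0), bDMI = bBF = 0 (the study found no intervention
effects), self-efficacy within/between 462/263, motivation variant
390/1756, barriers −48/926, pain −1524/−4059, τ00 = 7,994,000,
σ² = 6,006,000 (ICC exactly 0.571), τ11 = 1158, τ01 = 703, ρ = 0.15.
The variance *levels* are set so that (a) the ICC ratio is 0.571, (b)
per-participant means and day-to-day SDs match the ranges the study
reports (≈6,300–13,600 and ≈2,500–4,800 steps), and (c) the Gaussian
left tail almost never crosses zero — a visibly larger zero-day mass
would be an artifact no step-count cohort shows, and the floor would
then bias within-person effect recovery.  Published residual-variance
entries for these models are conditional quantities from discrepant
tables and do not pin the absolute level; where printed values conflict
(the three random-covariance entries disagree by orders of magnitude),
the predictor-model table is preferred.

Missingness is MCAR: one participant loses all step data with
probability 1/15, remaining person-days lose steps at 30/560, and each
EMA *questionnaire* (morning: self-efficacy, motivation, barriers;
evening: motivation, pain) is skipped at 0.10/day — apps lose whole
prompts, not single items, and per-item completion percentages in such
studies move together within a prompt.  Engagement (dMI used ~73% of
windows; BF on-time 0.75 / one-day-late 0.06 / never 0.19 per window,
late uploads landing on the wash-out day) feeds the adherence summaries
only; all analyses use intention-to-treat availability coding.

What the generator does *not* emulate: reactivity and learning effects,
MAR/MNAR missingness (a switch exists for none of it; the real study's
missingness was not MCAR), within-day 10-minute step streams,
non-Gaussian step distributions, and floor/ceiling behavior of the EMA
scales beyond discretization.  Passing recovery tests therefore shows
the *estimators* work under the assumed data-generating process, not
that the process matches any particular real cohort.

## Per-participant dynamic regression

Each participant's series is analyzed alone.  Screening: (1) linear and
quadratic time trends by coefficient p-value (< .05) in curve-estimation
fits; (2) a weekday cycle via a single numeric weekday covariate
(1=Mon..7=Sun) — the aggregated models instead use categorical dummies,
and the numeric coding here mirrors the one-coefficient-per-participant
reporting convention; (3) autocorrelation lags 1–7 screened against the
±1.96/√n white-noise band and confirmed by the lagged-steps regression
p-value.  The final OLS model adds the two availability indicators (or
one EMA predictor) plus barriers and pain controls and any retained
screen terms; wash-out days stay in as de-facto control days; rows with
any missing variable are dropped listwise; covariates that are constant
for a participant (e.g. never-reported pain) are dropped and recorded
rather than raised.  Inference is t-based; a perfectly fitting model
reports P = 0 for non-zero coefficients instead of dividing by zero.  No
multiple-testing correction is applied across participants; cohort
summaries report k/n (percent) counts of significant coefficients by
sign.

## Aggregated multilevel models

The six-model ladder (fit by `run_ladder`) is described in `mlm.py`'s
module docstring.  Key choices:

- **ML for the ladder, REML for inference.**  Deviance comparisons
  across models differing in fixed effects require ML, and all reported
  −2LL/BIC/chi-square values are ML quantities (BIC counts all estimated
  parameters, k = fixed + variance).  But ML variance components are
  biased low by roughly (m−q)/m with m = 15 participants and q = 4
  person-level fixed terms, which would shrink every person-level
  standard error by ~15%.  Each fit therefore re-estimates the variance
  parameters under the restricted (REML) criterion, warm-started at the
  ML optimum, and draws all standard errors, CIs and reported variance
  components from that step.  Recovery simulations show τ00 estimated
  essentially without bias this way.
- **Kackar–Harville covariance correction.**  The plug-in GLS covariance
  ignores uncertainty in the estimated covariance parameters; the
  first-order correction D·Cov(θ̂)·Dᵀ (D = numerical derivative of the
  GLS coefficients with respect to the covariance parameters, Cov(θ̂)
  from the numerical REML Hessian) is added to the fixed-effect
  covariance.  It matters mainly for person-level terms.
- **Degrees of freedom** follow the between/within rule: person-constant
  columns get m − q, day-varying columns get N − p.  The original SPSS
  Satterthwaite df are approximated, not matched.
- **Gap-aware AR(1).**  The residual correlation between two of a
  participant's rows is ρ^|day difference|, so rows removed by wash-out
  exclusion or missingness widen the gap instead of becoming adjacent.
  This keeps the wash-out-excluded intervention analysis coherent with
  the same underlying daily process.
- **One common complete-case frame per ladder.**  All six models are fit
  on the rows complete for the largest model's variables, so successive
  deviance tests compare identical data and the deviance is
  monotonically non-increasing along the ladder.  Fitting each model on
  its own maximal frame would make the chi-square tests incomparable.
- **Optimization.**  β and σ² are profiled out; the remaining ≤4
  parameters (relative covariance Cholesky on log scale, ρ via tanh) are
  optimized with L-BFGS-B in a batched, zero-padded all-participants
  evaluation, with a Nelder–Mead polish and perturbed restarts as
  safeguards and warm starts along the ladder.  Variance estimates at
  the transform boundary are reported at (numerical) zero with a
  `boundary` flag; no boundary-mixture correction is applied to deviance
  tests.

## Little's MCAR test

EM for the multivariate-normal mean/covariance under arbitrary
missingness (tolerance 1e-8 on the observed-data log-likelihood, max 500
iterations), then the usual pattern-wise quadratic form with
df = Σ k_j − k.  Complete data returns χ² = 0, df = 0, P = 1.  The
variable set is configurable (steps plus the five EMA items by default);
the df any particular published analysis used is generally not
reconstructable from a report, so no specific printed statistic is
targeted.

## Monte-Carlo harness

Per-replicate seeds derive from the master seed via
`SeedSequence(master, spawn_key=(stream, rep))`, making every replicate
independently re-runnable.  Recovery experiments report truth, mean
estimate, bias, RMSE, MC standard error and CI coverage per parameter;
fit failures are counted, never hidden.  Problem sizes in the shipped
tests and acceptance script — 200 replicate cohorts for recovery, 1000
for type-I error — give MC standard errors of ≈5 steps/point on the
recovered within-person effects and ≈0.007 on rejection rates; coverage
estimates from 200 replicates carry ≈±0.02 of binomial noise, and the
tests judge the coverage band at that precision.

## Known limitations

- Between-person effects are estimated from 15 person-level points; their
  estimates are valid but very noisy (as in the original analyses), and
  their CI coverage relies on the REML + Kackar–Harville corrections.
- The aggregated type-I rate of the intervention test runs slightly
  above nominal (≈0.06 at α = .05) — small-m Wald inference; the
  per-participant test is well calibrated.
- The generator's AR(1)-Gaussian residual is an idealization; robustness
  to skewed or heteroscedastic step noise is untested.
- SPSS MIXED internals (Satterthwaite df, its convergence path, exact
  printed variance components) are out of scope by design.
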
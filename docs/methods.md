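# Methods

`habitdecay` analyses habit degradation from intensive-longitudinal SRBAI
diaries. This note records the models, the calibration of the synthetic
cohort, the numerical choices, and what the tests do and do not establish.

## Study design emulated

A 91-day diary study: baseline on day 0, cue-identification days 1–6,
initial habit-strength measurement and randomization on day 7, then daily
end-of-day SRBAI items through day 91. Seven arms — control (n = 50) and
the 3×2 factorial of strategy (substitution, inhibition, reduced
accessibility) × reward (yes/no) with 43–44 per cell — totalling 313
participants and 313 × 85 = 26,605 scheduled prompts. Time is centered at
the day-7 measurement, so t runs 0–84.

## Synthetic cohort generator

Each participant carries a latent trajectory
`y(t) = asym + (r0 − asym)·exp(−exp(lrc)·t)` with person-level draws:

| parameter | distribution (default) | units |
|---|---|---|
| r0 (initial level) | Normal(2.57, 0.55), truncated jointly | score 0–4 |
| asym (lower asymptote) | Normal(1.38, 0.70), truncated jointly | score 0–4 |
| lrc (log rate constant) | Normal(ln 0.023, 1.0); +1.05 in intervention arms | ln(day⁻¹) |

Pairs (r0, asym) are resampled until 0 ≤ asym ≤ r0 ≤ 4; this truncation
raises the realized day-7 mean from 2.57 to ≈2.63, which is why the raw
draw mean sits below the target. Observed items are latent + day-level
noise (sd 0.08) + item-level noise (sd 0.25), rounded to the 0–4 Likert
grid. When both noise sds are zero the generator emits the latent value
un-rounded, giving an exact-evaluation mode for tests.

Missingness is an independent per-day Bernoulli with response probability
`logit⁻¹(1.01 − 0.022·t)`, falling from ≈0.73 at t = 0 to ≈0.30 at t = 84
and integrating to ≈52% overall completion. One exception: the first diary
day always responds, because the day-7 measurement doubles as the
randomization-visit initial score that every enrolled participant provides.
Response timestamps are drawn 82% same-evening (19:00–23:59), 15%
next-morning (00:00–10:30, recoded back one day during preprocessing), 3%
midday (the exclusion band), independent of scores (missingness is
completely at random given time).

### Calibration rationale

The generator's defaults were fixed once, against four cohort-level
targets: day-7 composite mean ≈ 2.63; overall completion ≈ 52%; latent
week-1 mean rates ≈ −0.04 (control) and ≈ −0.085 (intervention); and
spline-estimated full-sample weekly rates ≈ −0.055 (week 1) and ≈ −0.03
(week 2). The latent and spline-estimated rates cannot coincide:
generalized cross-validation smoothing attenuates early derivatives of a
noisy exponential by roughly a third at these noise levels and sampling
densities (we verified that R's mgcv reproduces our smoother's effective
degrees of freedom and derivatives almost exactly, so the attenuation is a
property of the method, not of this implementation). The calibration
therefore places the latent intervention rate near −0.085 so that both the
latent and the smoothed summaries land in realistic ranges. A side effect
of the modest noise this requires is that most synthetic trajectories pass
the RMSE ≤ 0.33 validity bound — real diary data are noisier and more
heterogeneous, so validity and reached-asymptote fractions from this
generator should not be read as realistic prevalence estimates.

What the generator does *not* emulate: event-contingent (cue-encounter)
records and reward delivery; person-varying noise levels; non-monotone or
rebounding trajectories; missingness that depends on habit strength.
Passing tests therefore show the pipeline's correctness and its behaviour
under the intended signal structure, not robustness to those features.

## Preprocessing

A response is assigned to a study day by clock time: [19:00, 24:00) →
same day; [00:00, 10:30] → previous day; (10:30, 19:00) → excluded. Both
boundary instants are treated as valid (the stated window is inclusive).
The composite requires all four items. When several valid responses map to
one day, the earliest is kept — it is the closest to the scheduled prompt.
Final habit strength is the mean over t ∈ [78, 84]; if that week is empty,
the last observation is carried forward. BMI (kg/m², from self-reported
weight and height) is winsorized at mean + 3 SD, the SD computed before
replacement; intention is the mean of its two items.

Reliability uses a person × day × item variance decomposition estimated by
ANOVA method-of-moments (balanced-design expected mean squares with
average counts for mild unbalance). Between-person reliability of person
means over n days and k items is `s²_P / (s²_P + s²_PD/n + s²_E/(nk))`;
within-person (day-level) reliability is `s²_PD / (s²_PD + s²_E/k)`. These
estimators are validated by recovering known simulated variance
components, not against any external figure.

## Asymptotic stage

Fitting is deterministic multi-start nonlinear least squares: for each of
25 log-spaced rate constants in [0.01, 1] the two level parameters are
solved linearly in closed form; the three best starts are polished with a
bounded trust-region solver (levels constrained to [−1, 5], slightly
beyond the scale, to keep short noisy series from diverging; lrc in
[ln 1e−4, ln 10]). Fewer than three observations, or solver failure, yield
a non-converged fit, which is non-valid downstream. "Approaches a lower
asymptote" is operationalized as r0 − asym > 1e−6 — a tolerance that
exists only to classify numerically flat fits as non-decreasing.
t95 = ln(20)/exp(lrc) is reported as a continuous value; a 0.01-day grid
scan of predicted values serves as the independent test oracle. The
reached-95% dummy compares t95 to the participant's *last observed* t, not
to day 84: the dummy describes what the observed series shows.

## Spline (GAM) stage

Cubic B-splines on [0, max t] with interior knots at quantiles of the
observed days; basis dimension from the observation-count rule (5, 10, 15).
"Knots" means basis dimension, the convention of the dominant GAM
toolchain. The penalty is the exact integrated squared second derivative
(two-point Gauss per knot span); the smoothing parameter minimizes GCV
`n·RSS/(n − edf)²` over a 49-point log grid, with a 1e−9 ridge for rank
safety. Derivatives are analytic (B-spline coefficient differencing), never
finite differences, and evaluation outside the fitted range raises.
Weekly rates average the derivative at integer days 0–6 and 7–13 — the
days the diary design samples; a dense-grid (0.01-day) variant is provided
and agrees within ~1e−3 on smooth fits. Windows truncated by a short
series use only covered days; an uncovered window is missing. Sufficiency
requires an observation in week 1, in week 2, and after week 2.

## Group inference

Linear models use Type III sums of squares with sum-to-zero contrasts —
the factorial is unbalanced and main effects are reported alongside the
interaction. Generalized eta squared is SS_effect/(SS_effect + SS_error).
Adjusted means weight factor levels equally with the covariate at its
grand mean. The intervention-vs-control contrast pools all six
strategy×reward arms against control. Logistic models report Wald z for
single-df effects and likelihood-ratio χ² (dropping the term under sum
contrasts) otherwise; adjusted probabilities are inverse-logit predictions
with delta-method SEs (p(1−p)·SE of the linear predictor) and CIs
back-transformed from the logit scale. Days-to-95% is analysed on the log
scale; back-transformed means use SE_back = exp(mean_log)·SE_log and
exponentiated (asymmetric) CIs. Missing outcomes are never imputed — they
are intentionally missing by stage criteria — and logistic missingness
checks regress each outcome's missingness indicator on group and
intention.

Holm adjustment is step-down with a *declared* family size: the family for
an outcome can exceed the number of p values supplied (unobserved members
count toward the multiplier). The default families are 3 (magnitude), 3
(asymptote likelihood), 6 (weekly rates: two weeks × three effects), 3
(days). Note that step-down Holm gives the second-smallest member of a
family `max(smallest·m, second·(m−1))`, not `second·m`.

## Equivalence and power

TOST uses two one-sided t tests against the ROPE bounds; p_tost is the
larger one-sided p, paired with a 90% CI and the three-way rule: accepted
if the CI lies inside the ROPE (inclusive), rejected if it excludes zero,
undecided otherwise. Factor equivalence uses pairwise adjusted-mean
contrasts against a reference level (reduced accessibility for strategy,
no-reward for reward), averaged over the other factor with equal weights.
The ±1-day SESOI for days-to-95% becomes a log-scale ROPE
[ln((m−1)/m), ln((m+1)/m)] anchored at the reference group's
back-transformed adjusted mean m — a reconstruction, since a ±1-day band
has no scale-free log form; it is undefined when m ≤ 1.

Power detection simulates the design with a true effect equal to the
SESOI and the observed per-cell n and SD, and reports the rejection rate
of the matching analysis at α = 0.05 with its Monte-Carlo SE. Two-arm
continuous designs use the pooled t test (identical to the one-way F) and
two-arm binary designs the closed-form 2×2 Wald statistic (the saturated
logistic MLE), both fully vectorized; factorial designs loop over
statsmodels fits. The binary simulations use a baseline prevalence of 0.22
for reaching the asymptote threshold. The pipeline default is nsim = 1000
(Monte-Carlo SE ≤ 1.6 points), chosen so a full 313-person end-to-end run
completes in a few minutes; nsim is a parameter wherever power is
computed.

## Determinism

Every stochastic stage consumes a seed derived from the master seed
(numpy `SeedSequence` spawning per participant; per-battery seeds for
power), so the full pipeline is bit-for-bit reproducible and any single
stage re-runs identically from its persisted CSV/JSON inputs.

## Known limitations

- Person-by-person fitting only; no partial pooling across participants,
  by design — outcomes must be extractable per person.
- The negative-exponential form cannot represent rebounds or stepwise
  drops; such trajectories surface as high RMSE (non-valid) rather than as
  alternative fits.
- GCV occasionally oversmooths short, noisy series; the weekly-rate
  estimates inherit the attenuation discussed under calibration.
- The reliability estimator assumes near-balanced data; heavy unbalance
  biases the method-of-moments components.
- The log-days ROPE anchoring and the binary power simulation model are
  reasoned reconstructions of standard practice, documented here rather
  than taken from any single authoritative formula.
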
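# Methods

## The estimation problem

In ageing cohorts, the association between body-weight change and mortality is
distorted by reverse causation: chronic illness causes both weight loss and death,
and is itself partly a consequence of earlier weight change. Chronic illness is
therefore a *time-varying confounder with treatment–confounder feedback* — it
satisfies all three classical criteria: weight status predicts illness onset,
illness predicts subsequent weight change, and illness independently predicts
mortality. Conditioning on such a variable in a regression removes confounding but
also adjusts away the part of the weight-change effect that illness mediates;
leaving it out leaves the confounding in place. The standard resolution is a
marginal structural model (MSM): reweight the observed person-periods by stabilized
inverse probabilities of the observed exposure so that, in the weighted
pseudo-population, exposure is independent of the measured time-varying confounders,
then fit an unconditional (marginal) hazard model.

## Data structure and preparation

The unit of analysis is the person-period: subject `i` contributes one row per
interval `t` (wave `t` to `t+1`), carrying

- the exposure `A_t`: the five-level category of percentage BMI change between
  waves `t−1` and `t` (large loss ≤ −10%, small loss (−10, −5], stable (−5, 5),
  small gain [5, 10), large gain ≥ 10%; the loss-side boundary convention keeps
  "≥ 10% loss" literal and the categories disjoint),
- baseline covariates `V` from wave 1 (sex, entry age, race, education, baseline
  BMI category by the WHO cut-offs 18.5/25/30/35, baseline smoking, self-rated
  health, illness, marital status, log household income),
- time-varying confounders `L_{t−1}` at their wave-(t−1) values (illness ever,
  self-rated health, smoking, vigorous activity, marital status, log income) —
  lagged one interview so that confounders precede the weight change,
- the interval death indicator `Y_t` and censoring indicator `C_t`.

The exclusion cascade mirrors the analysed cohort's: death or dropout before wave 2,
missing BMI at any attended wave, baseline BMI > 60, and any between-wave loss
greater than 30%, applied sequentially with each subject counted once at the first
rule that removes it. A missed interview truncates follow-up at the last pre-gap
wave (treated as dropout); subjects are not re-entered.

## Weights

The denominator model is a multinomial logit of `A_t` on `V`, `A_{t−1}` and
`L_{t−1}`; the numerator (stabilizing) model conditions on baseline demographics
and `A_{t−1}` only. The weight for row `t` is the running product over `s ≤ t` of
the numerator-to-denominator ratio of the predicted probability of the exposure
actually observed at `s`. Censoring weights are built the same way from pooled
logistic models of the censoring indicator and are on by default; because a subject
censored in `(t, t+1]` still contributes row `t`, the censoring ratio enters the
product one interval late. Final weights are truncated at the 1st/99th percentiles
(configurable; truncated rows are flagged and counted). A denominator probability
below 1e−6 raises a positivity error rather than being clipped, so pathological
scenarios surface instead of silently distorting a fit.

## Outcome model

A pooled logistic regression of `Y_t` on interval dummies (the discrete baseline
hazard), the four exposure dummies (stable reference), the four baseline-BMI
dummies (normal reference) and design-specific baseline covariates, weighted by the
stabilized weights, with a subject-clustered sandwich covariance for the repeated
measures. With biennial intervals and per-interval event probabilities of a few
percent, exponentiated coefficients are hazard ratios in the proportional-hazards
sense (verified in the tests against a continuous-time counting-process fit, which
agrees within 5%). 95% CIs use ±1.96 robust SEs; significance stars at
.05/.01/.001.

The four designs form the incremental sequence: M1 — weight terms only, unweighted;
M2 — adds socio-demographic/SES covariates (baseline values in the outcome model,
lagged SES in the weight denominator); M3 — adds health behaviors (smoking,
physical activity); M4 — adds health conditions (chronic illness, self-rated
health). Time-varying confounders never enter the outcome model directly; their
baseline values do, and their lagged values act through the weights alone.
Stratified fits (by ever-smoking or baseline weight category) refit both the
weights and the outcome model within each stratum, dropping stratum-constant
covariates (which are inestimable by construction) and, for the baseline-weight
stratification, the baseline-BMI dummies; a stratum that still cannot be fit is
reported as unestimable rather than failing the run. Interaction fits add
modifier × (exposure, baseline-BMI) products to the pooled model with Wald tests
from the robust covariance; for the smoking modifier the ever-smoker indicator
replaces the three-level smoking factor it is otherwise collinear with.

## The synthetic cohort

The study's source data are restricted, so the test bed is a generator that
emulates the relevant structure: entry ages uniform on [50, 60], ten biennial
waves, baseline BMI from a three-component normal mixture (≈1% underweight, ≈35%
normal, ≈40% overweight, ≈15% class-I, ≈6% class-II/III obese), and logistic /
multinomial-logistic transition models whose functional forms match the analysis
models, so the denominator model is correctly specifiable and weighting correctness
is isolated from misspecification. Within a wave the order is: smoking transition,
income random walk, marital transitions, illness onset (on previous BMI category,
prior weight-change category, smoking, age), self-rated health (on illness and
prior weight change), then the weight-change draw (multinomial on baseline
covariates, prior exposure and *lagged* illness/srh/smoking/activity), the
within-category percentage uniform inside the category bounds with losses capped at
30% to stay inside the analysed support. Death in `(t, t+1]` is drawn after the
wave-`t` exposure is realized (current exposure affects current-interval
mortality), from a logistic model with baseline-BMI and current-exposure log-HRs
plus illness, poor self-rated health, smoking and age terms. Dropout depends on
lagged health and income only, so censoring models using observed history are
correctly specified; a dropout draw is made at every wave including the last, which
keeps the censoring hazard specifiable without interval terms.

Presets:

- **confounded** — illness→loss and loss→illness feedback with structural exposure
  log-HRs ordered large loss (0.79) > large gain (0.47) > small loss (0.34) >
  small gain (0.14) > stable (0), and a strong mediated pathway (prior weight
  change raises illness onset and worsens self-rated health; episodes persist).
  Cumulative mortality ≈ 35% over ten waves — higher than the emulated survey's
  ≈20%, a deliberate trade for event counts at n = 3,000.
- **null_effect** — every causal path from exposure to death is cut (structural
  log-HRs zero, illness/srh feedback zero, BMI-level effect on illness onset
  zero) while illness→exposure and illness→death confounding remain: the hard
  null for type-I-error calibration. The feedback terms must be cut too because
  a mediated path would otherwise leave the *total* effect nonzero.
- **no_feedback** — illness onset independent of prior weight change.
- **strong_reverse_causality** — illness→large-loss and illness→death inflated.

What the generator does **not** emulate: measurement error in self-reported
height/weight, item nonresponse patterns beyond missing-at-random BMI, survey
design weights, cause-specific mortality, and the real survey's marginal
distributions beyond qualitative direction. Passing tests therefore demonstrate
that the estimator recovers known truths under correctly specified treatment–
confounder feedback of realistic magnitude — not that any particular real-data
estimate is right.

## The oracle (ground truth)

The estimand of the weighted analysis is defined on the pseudo-population in which
exposure follows the stabilizing distribution. The oracle computes it directly: fit
the numerator multinomial on a large confounded draw, then re-simulate the same
world with exposure assigned from that fitted distribution (cutting every
confounder arrow into exposure, leaving illness dynamics, mediation and mortality
untouched) and without dropout — the censoring-weighted analysis targets the
no-censoring world — and fit the marginal pooled hazard model there. With 120,000
oracle subjects the truth's Monte-Carlo SE is ≈0.015–0.020 per log-HR,
an order of magnitude below the replicate-level SEs (≈0.1–0.2 at n = 3,000), so
treating the oracle point estimates as truth adds negligible error to coverage and
bias measurements.

## Study sizes and Monte-Carlo error

The replicate studies use n = 3,000 subjects per replicate with 50 confounded, 200
null and 30 reverse-causality replicates; these sizes keep a full single-CPU run in
minutes. At 50 replicates the pooled-coverage estimate (8 parameters × 50
replicates) has binomial SE ≈1.1 points (correlation within replicates makes the
effective SE somewhat larger); per-parameter coverage has SE ≈3 points, which is
why acceptance is asserted on the pooled rate and the per-parameter values are
reported. At 200 null replicates a true 5% rejection rate is estimated with SE
≈1.5 points. The mean-absolute-bias statistic carries MC noise ≈0.01–0.015 on the
log-HR scale.

## Numerical choices

- Multinomial fits use Newton with an L-BFGS fallback (Newton can diverge on
  near-separated draws); a solution is accepted when the flag or the score norm
  (<1e−3) says so.
- The weighted cluster sandwich from the GLM is used as-is; it was cross-checked
  against a hand-computed weighted estimating-equation sandwich.
- Weight truncation default (1, 99) percentiles; positivity floor 1e−6, hard error.
- Log-income is ln(income+1)-scale throughout the generator (zero incomes never
  arise there; the preparation module takes income as already log-scale).
- Within-stratum refits prune stratum-constant covariates; the exposure, interval
  and prior-exposure factors are never pruned and fail loudly instead.
- Ties/boundaries: BMI category intervals closed on the left; a loss of exactly
  10% is a large loss, exactly 5% a small loss.

## The conventional comparator

`fit_naive_timedep` is the adjustment strategy the weighting replaces: an
unweighted pooled hazard model with the time-varying confounders entered directly
at their current-interview values (the values measured after the weight change,
which is what conditioning-on-a-mediator means in this timing). On the confounded
and reverse-causality presets its loss-category estimates sit systematically closer
to HR = 1 than the weighted estimates — it adjusts away the mediated component —
which is the qualitative signature the diagnostics reproduce.

## Known limitations

- The generator and analysis share functional forms; robustness to
  misspecification of the denominator model is not studied here.
- The oracle's pseudo-population uses a numerator fitted on one large confounded
  draw; replicate-level numerators differ slightly, contributing a small (<0.01)
  systematic component absorbed by the coverage band.
- Weight-estimation uncertainty is ignored by the sandwich (standard practice;
  typically conservative).
- Survey weights, multiple imputation and cause-specific mortality are out of
  scope.
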
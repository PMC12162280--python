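# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts can and cannot establish about real clinical data.

## Data model and preprocessing

A cohort is a raw feature table (continuous labs, categorical covariates
with explicit reference levels) plus ±1 labels, +1 meaning relapse within
3 years.  Continuous features are z-scored with training-fold mean and
sample standard deviation (denominator n − 1); categorical features are
one-hot encoded with the reference level dropped (all-zero block), matching
regression coding.  Scaling is a deliberate choice rather than a neutral
one: unscaled laboratory magnitudes (platelets ~10², neutrophils ~10⁰)
would dominate the Gaussian and sigmoid kernels.  Preprocessing parameters
are learned on the training fold only and applied frozen to validation and
test folds; the screening regressions, by contrast, run on the natural
scale so odds ratios are per clinical unit.

Age enters dichotomized at 50 years by default (the schema supports a
continuous column if preferred); labels are accepted as {0,1} or {−1,+1}
and canonicalized to {−1,+1}.

## Synthetic cohort generator

The generator emulates the study schema: categorical covariates from
configurable multinomials, Gaussian labs, NEU and PLT drawn bivariate
Gaussian with correlation 0.8 by default — a deliberately induced
collinearity so the screening filter has a true positive to find — and a
Bernoulli outcome from a logistic model.  Default coefficients are the
natural logs of the published multivariate odds ratios (age>50 0.419,
stent 0.419, catheter-directed thrombolysis 2.57, TIPS 0.809, NEU 1.197,
ALB 0.967, AFP 0.92 per unit); all other covariates carry coefficient
zero.  The intercept is calibrated by Monte-Carlo root finding
(200,000 covariate draws, Brent's method on [−20, 20]) so the expected
prevalence matches 169/522.

Category probabilities and lab means/sds are plausible placeholders
(e.g. NEU 4.2 ± 1.8 ×10⁹/L, ALB 38 ± 5 g/L), not estimates of the source
cohort, whose per-feature distributions are not published numerically.
Gaussian tails can produce clinically implausible values (including
negative labs); they are left unclipped so that logistic parameter
recovery is exact.  An optional log-normal AFP matches the requested
mean/sd on the natural scale.  The generator does not emulate follow-up
times, censoring, measurement error, or covariate interactions — so
passing recovery tests demonstrate correctness of the pipeline under its
own assumptions, not predictive validity on hospital data.

## Screening statistics

Continuous two-group comparisons are gated on Shapiro-Wilk normality per
group at α = 0.05: both normal → Welch t-test (no equal-variance
assumption), otherwise Mann-Whitney U with the tie-corrected normal
approximation; groups under 3 observations skip the gate and use
Mann-Whitney.  Categorical variables use uncorrected Pearson chi-square
(Yates by flag).  The collinearity filter computes Pearson correlations
among candidate labs and, for each pair with |r| ≥ 0.7 (strongest pair
first), drops the member whose group-comparison p-value is larger.

Logistic regression is maximum likelihood via IRLS/Newton (tolerance 1e-8
on the log-likelihood, max 100 iterations) with Wald standard errors from
the inverse Fisher information; odds ratios exp(β) with 95% CI
exp(β ± 1.96·SE).  Non-convergence or any |coefficient| > 15 is treated
as separation and raised as an error naming the offending column;
identically-zero columns are excluded, so an empty design degrades to the
intercept-only model.  Univariate screening selects a variable when any
non-reference term reaches p ≤ α; the multivariate stage uses backward
elimination at α = 0.05, judging categorical variables by their minimum
level p and dropping them as whole blocks.  Backward elimination is this
package's documented choice — the selection algorithm behind the published
multivariate table is not stated.

## Multi-kernel learner

Base Grams are scale-equalized by trace normalization K·n/|tr K| before
combination (|·| because the indefinite sigmoid kernel can have a negative
trace); the normalization factor learned on the training Gram is reused
for test cross-Grams.  The γ problem

    min_γ (1−φ) γᵀŶKŶγ + φ‖γ‖²  over  {γ ≥ 0, per-class sums = 1}

is solved by pairwise coordinate descent: every same-class pair (r, q),
visited in a seeded shuffled order per sweep, takes the step
ε* = −(g_r − g_q)/(A_rr + A_qq − 2A_rq) with A = (1−φ)ŶKŶ + φI and
g = Aγ, clipped to [−γr, γq]; when the pair curvature is non-positive
(possible with the sigmoid kernel) the better feasible endpoint is taken.
The sweep order is built over index pairs rather than per class, which
makes the solve invariant under a global label flip (mirrored problems
produce exactly negated scores).  Convergence: objective improvement of a
full sweep < 1e-7, cap 500 sweeps.  At φ = 1 the solution is the uniform
per-class vector, a useful closed-form check.

Kernel weights follow the two-stage EasyMKL rule: solve γ on the
unweighted average Gram, set ηₘ ∝ max(γᵀŶKₘŶγ, 0) normalized to the
simplex (uniform fallback if all margins vanish), then re-solve γ on the
η-weighted composite.  The bias is the KOMD-style midpoint of the
γ-weighted class-mean unbiased scores.  Scores map to risks by Platt
scaling fitted on training-fold scores with a bounded Newton iteration;
coefficients are capped at ±15 because separable score distributions push
the MLE to infinity, and risk outputs are clipped to the open unit
interval at machine precision.  The operating risk threshold defaults to
0.59 and is configuration, not a derived quantity; the evaluation
protocol instead selects a Youden-optimal threshold on validation risks.

## Hyperparameter search

PSO with the protocol constants: 10 particles, 10 iterations, inertia
ψ = 0.9, cognitive and social factors 2, one scalar U(0,1) draw for each
of r1, r2 per particle per update.  Search bounds (chosen to span the
regimes where each kernel changes behaviour on z-scored features):
offset ∈ [0, 10], degree ∈ [1, 5] rounded to integer at evaluation,
α and σ ∈ [1e-3, 10] log-uniform, β ∈ [−10, 0], φ ∈ [0.01, 0.99].
Velocities start at zero, are clamped to half the box width, positions are
clipped to the box.  The default-hyperparameter candidate is injected into
the initial swarm so tuning never returns something worse than defaults on
the folds evaluated; objective failures and non-finite values count as −∞
with a logged warning.

## Evaluation protocol

Splits are 6:2:2 with floors to train and validation and the remainder to
test (313/104/105 at n = 522), stratified by label by default: the global
part sizes are fixed first, the positive class is allocated by largest
remainder (ties toward later parts) and the negative class takes the
complement, so part totals are exact for any label realization.  AUC is
the Mann-Whitney rank statistic (ties at ½); sensitivity, specificity and
accuracy are computed at the validation-Youden threshold with the
"risk ≥ t → positive" rule; empty denominators yield NaN, not zero.
Each round re-splits with seed base+r, re-tunes, re-fits, re-evaluates; a
failed configuration-round is logged and excluded from that
configuration's aggregate rather than aborting the experiment.  Baselines
(random forest, XGBoost, k-NN through a fit/score adapter contract) run on
the identical splits and thresholds.

Problem sizes in the shipped tests are chosen to keep the whole suite a
desk-scale exercise: the full 15-configuration protocol runs 2 rounds on a
522-patient cohort, parameter recovery uses one 20,000-patient cohort, and
solver-oracle comparisons use n = 4 instances where the feasible set is a
2-D square that a dense grid can cover.

## Attribution

Shapley values are computed on the risk scale at the level of clinical
variables: a categorical one-hot block moves as one player.  The sampling
estimator draws a feature ordering and one background patient per
permutation, walks the ordering replacing background values with the
explained patient's values, and credits each risk increment to the feature
just inserted (200 permutations and up to 100 background rows by default).
It is exactly efficient in expectation; per-feature Monte-Carlo standard
errors are reported.  An exact 2^d coalition enumeration with the same
background-marginal value function is included for small d as a
verification oracle.  The permutation estimator was preferred over a
regression-weighted kernel estimator because it is directly comparable to
that enumeration.

## Known limitations

- The published headline performance (test AUC 0.831 on the hospital
  cohort) is not reproducible without the private data; synthetic results
  characterize the pipeline, not the clinical claim.
- The sigmoid kernel is indefinite; the solver handles non-convex pair
  directions by endpoint steps, so the γ "optimum" on sigmoid-heavy
  composites is a stationary point of a non-convex problem.
- Platt calibration on the training fold can be optimistic on small folds;
  the Youden threshold is chosen on validation risks to compensate.
- The PSO budget (110 evaluations) is a protocol constant, not a
  convergence guarantee; tuned hyperparameters are only argmax over the
  evaluated set.
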
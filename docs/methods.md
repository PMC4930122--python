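# Methods

This note documents the models, the synthetic-data generator, the
estimation machinery and the numerical choices behind the package, at the
level of detail a user would need to judge what the pipeline does and does
not establish.

## Task environment

The simulator implements the two-stage task with the constants fixed by the
study design: 201 trials per session (55 in the practice variant), a fixed
transition probability of 0.7 from each first-stage action to its common
second-stage state (the action-to-state map is the identity bijection; which
physical stimulus pair is "state 0" is an arbitrary labeling), exponential
intertrial intervals with mean 2 s, a 2-s decision window per stage, a 1.5-s
first-stage display period and a 1-s feedback display. Onset times accumulate
these durations, so event onsets strictly increase within and across trials.

Reward probabilities of the four second-stage options evolve as independent
Gaussian random walks. Their parameters are not printed in the study text
(which defers to the original description of the paradigm), so the
conventional values are adopted and exposed in `TaskConfig`: innovation SD
0.025 per trial, reflecting boundaries at [0.25, 0.75], initial values drawn
uniformly within bounds. Reflection (rather than truncation) is used because
truncation piles probability mass onto the bounds and changes the stationary
distribution; under reflection it is approximately uniform, which the tests
verify by Monte Carlo.

## Observation models

All three models share the second-stage value table and its update
`Q2[s2,a2] += alpha2 * (r - Q2[s2,a2])`. The model-free controller is
SARSA(lambda) with the two-stage eligibility form applied once per trial at
trial end:

    delta1 = Q2[s2,a2] - Q1[a1]
    delta2 = r - Q2[s2,a2]
    Q1[a1] += alpha1 * delta1 + alpha1 * lambda * delta2

The additive form (delta1 term plus lambda-weighted delta2 term) follows the
canonical formulation of the paradigm; it is isolated in `mf_update` so that
a variant (e.g., replacing rather than adding) would be a one-line change.
The model-based controller recomputes first-stage values prospectively every
trial from the instructed transition probabilities and the current maxima of
Q2; it learns nothing at the first stage, so `alpha1` and `lambda` are inert
when omega = 1. The hybrid controller mixes the two first-stage value
vectors with weight omega. The stage-1 policy is a softmax over
`beta1 * Q + rho * repeat-indicator`, where the perseveration bonus applies
only to repeating the previous trial's first-stage choice (zero on the first
trial); the stage-2 policy is a softmax over `beta2 * Q2[s2]`.

Values are initialized at 0.5 everywhere — the midpoint of the
reward-probability bounds — so the very first prediction errors carry no
systematic sign bias; this is exposed as `TaskConfig.q_init`.

Invalid trials (no response within the window) are supported throughout the
I/O, likelihood and regressor paths: they contribute no likelihood terms,
trigger no value updates (nothing was observed), break stay-probability
pairs, and are emitted as separate unmodulated regressor events. The
generator itself produces only valid trials; misses are a property of human
data the synthetic cohorts do not emulate.

## Synthetic cohorts

Cohorts are the package's study conditions: 24 "high-impulsive" and 26
"low-impulsive" subjects, each parameterized by draws from truncated normal
distributions on the native scale. The means/SDs of the four hybrid learning
parameters (omega, alpha1, alpha2, lambda) are the published group-level
estimates for the two groups; redrawing (not clipping) out-of-range values
keeps the stated means approximately intact. The softmax and perseveration
parameters have no published group values, so defaults were fixed once at
magnitudes typical of fitted values on this task family: beta1 ~ N(5, 1.5)
and beta2 ~ N(4, 1.5) truncated to [0, 20], rho ~ N(0.2, 0.2) unbounded.
Per-subject seeds derive from the global seed as `seed + subject index`, so
cohorts are bit-reproducible and stable under subsetting.

What the generator emulates: the trial structure, transition statistics,
drifting rewards, and between-subject parameter heterogeneity. What it does
not: response times, attention lapses and missed responses, learning of the
transition model (agents know the true 70/30 structure, as instructed
participants do), within-session parameter drift, and any coupling between
parameters and group beyond the specified means/SDs. Passing tests therefore
demonstrate correctness of the machinery and the qualitative behavioral
signatures under ideal observers of this family — not that real participants
satisfy the model.

## Fitting

Parameters are estimated in an unconstrained space: logit for the
unit-interval parameters, log for the inverse temperatures, identity for
rho. Subject-level estimates are MAP optima of `nll(theta) - log N(x; mu,
diag(sigma^2))` found by multi-start L-BFGS (default 10 starts: the prior
mean plus prior draws; numerical gradients). The likelihood kernel is
compiled (numba) and cross-checked against an independent pure-python replay
to 1e-8.

The group prior is estimated by Laplace EM: the E-step computes each
subject's MAP and a Gaussian posterior approximation from the
finite-difference Hessian at the MAP (central differences, relative step
1e-3; if the Hessian is not positive-definite the fallback is the inverse
diagonal, then an identity-scaled covariance); the M-step sets the prior
mean to the mean of MAPs and the prior variance to the MAP scatter plus the
mean posterior variance, floored at 1e-4. After the first sweep the E-steps
are deterministic (warm start plus prior mean), which makes the fixed point
stable; iteration stops when the prior mean moves less than 2e-3 in max-norm
(about 5e-4 on the native scale — far below scientific relevance) or after
40 iterations, in which case a warning is raised and a non-convergence flag
returned. A diagonal prior covariance is used throughout: no correlation
structure is published, and a full covariance makes the EM fragile at n≈25.

Model evidence is the log of the average likelihood over draws from the
empirical prior (default 2000 per subject, log-sum-exp stabilized, fixed
per-subject seeds), with a delta-method Monte-Carlo standard error. Choice
probabilities are floored at 1e-300 inside the kernel so that extreme
temperature proposals yield large finite objectives rather than infinities.

## Model selection

Random-effects model selection uses the variational Dirichlet scheme:
responsibilities `u_nk ∝ exp(log-evidence_nk + psi(alpha_k) - psi(sum
alpha))`, counts `alpha = alpha0 + sum_n u_n` (alpha0 = 1 per model),
iterated to Delta-alpha < 1e-6. Exceedance probabilities are Monte-Carlo
(default 10^6 Dirichlet draws); for two models an exact Beta-marginal
computation is provided as a cross-check. Protected exceedance probabilities
(shrunk toward uniformity by the Bayes omnibus risk, computed from the
variational free energy against the equal-frequency null) are available but
off by default, since the headline analysis reports ordinary exceedance.

## Behavioral statistics

Stay probabilities condition the repetition of the first-stage choice on the
previous trial's reward and transition; the first trial contributes nothing,
and only consecutive valid pairs count. The 2 x 2 x group mixed ANOVA is
implemented through subject-level contrasts, which is exact when every
within-subject factor has two levels (no sphericity machinery needed): each
within effect is the unweighted grand mean of its contrast tested against
zero with the pooled within-group error, each effect-by-group term a pooled
two-sample t on the contrast, the group effect a two-sample t on the overall
mean stay level; every F is the square of its t with df (1, N-2). Degrees of
freedom are always computed from the data at hand. Subjects with an empty
stay-table cell are dropped with a warning (rare at 201 trials). The group
MANOVA reports Roy's largest root, the top eigenvalue of W^-1 B; with two
groups this is equivalent to Hotelling's T^2, so F = root * (N - p - 1)/p
with df (p, N - p - 1) is exact — verified against statsmodels' MANOVA to
1e-6. The directional between-group test on the reward main effect is a
pooled one-tailed t (high > low).

## fMRI regressors

Modulators are computed from each trial's *pre-update* values — the values
the prediction errors themselves are defined on. At second-stage onset the
model-free PE is delta1 (using the value of the *chosen* second-stage
action, the SARSA convention of this model family) and the difference
modulator is `Q_MB[a1] - Q_MF[a1]`, the partial derivative of the hybrid
value with respect to omega (hence identical for any omega). At feedback
the model-free PE is delta2 and the difference modulator is exactly zero,
because the two algorithms share second-stage values. Both PE time points
form one event stream, with feedback additionally modeled as a separate
unmodulated event; the difference modulator is mean-centered within subject
(the structural zeros at feedback are part of the centered stream).
First-stage onsets carry the softmax probability of the chosen action and
its omega-derivative `p(1-p) * beta1 * [(Q_MB - Q_MF)_chosen - (Q_MB -
Q_MF)_unchosen]`, verified against central finite differences.

Convolution uses the canonical double-gamma HRF (SPM parameterization via
nilearn; Glover optional, temporal derivatives optional and off by default)
on a 0.1-s grid, sampled at scan times with TR = 2 s; bit-compatibility with
any particular neuroimaging package is a non-goal. The default scan count is
900 (1800 s), which covers a full 201-trial session (mean duration ≈ 1710 s)
with margin; events beyond the window are dropped with a warning. Regressor
construction is a pure function of (session, parameters, config).

## Problem sizes and test design

The test suite exercises the full study scale where it matters and smaller
sizes elsewhere, chosen as a deliberate compute budget: calibration checks
use 10^5 draws; likelihood normalization is verified by exact enumeration of
a 2-trial task; parameter recovery runs one 50-subject cohort at 201 trials
with the full fitting settings; model-selection recovery runs 10 replicate
pipelines at 50 subjects with a reduced budget (6 restarts, 20 EM
iterations, 1000 evidence samples); the behavioral dissociation uses 500
sessions per pure-control cohort.

## Known limitations

* Recovery of omega and lambda from single 201-trial sessions is noisy and
  attenuated toward the interior: the alpha1·lambda product is well
  identified but its factors trade off, and omega trades against beta1.
  Group-mean MAPs are therefore mildly shrunk relative to generating means,
  and rank correlations between true and fitted omega/lambda sit near the
  recovery check's thresholds, fluctuating with the cohort seed. This is a
  property of the likelihood at this data size, not of the optimizer (the
  same attenuation appears in near-maximum-likelihood single-subject fits
  with a broad prior).
* The empirical prior is diagonal; correlated population structure would be
  absorbed into variances.
* Evidence by prior sampling is a simple estimator; its Monte-Carlo error
  (reported alongside) grows when the prior is much broader than the
  posterior.
* The ANOVA layer covers the 2 x 2 x 2 design only; covariate-adjusted
  models and trial-level logistic regressions are out of scope.
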
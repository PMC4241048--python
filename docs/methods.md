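# Methods

## Model and estimator

`imorsens` analyses a two-arm randomized trial with one binary outcome
`Y` that is missing for some participants (`R = 0`), optionally
stratified by a complete binary baseline covariate `X`.  It is a
pattern-mixture model: the outcome distribution is specified separately
for responders and non-responders within each `(X, Z)` cell,

    logit P(Y = 1 | X = x, Z = z, R = 1) = θ_xz,
    logit P(Y = 1 | X = x, Z = z, R = 0) = θ_xz + δ_xz.

The responder log-odds `θ_xz` are identifiable and estimated as
`logit(events / observed)` within each cell, with the binomial log-odds
variance `1/events + 1/non-events`.  The log IMORs `δ_xz` are *not*
identifiable — no amount of data informs them — and are supplied by the
analyst as extended reals.  `δ = 0` is MAR given `(X, Z)`; `δ = +∞`
forces every missing outcome to an event; `δ = −∞` to a non-event.  When
`X` is the baseline outcome state, `(δ_{0z}, δ_{1z}) = (−∞, +∞)` is LOCF.
Without a covariate the same model applies per arm.

The arm event probability is the count-weighted law-of-total-probability
combination of the four (cell × response-status) probabilities, and the
intervention effect is `g(p₁) − g(p₀)` with `g ∈ {logit, identity, log}`
giving the log odds ratio, risk difference and log relative risk.  All
three scales compare the same two arm probabilities, so they always agree
in sign.

Infinite `δ` are treated symbolically: the non-responder probability is
exactly 0 or 1 and contributes zero derivative.  This is what makes two
reductions *exact*, not approximate, and both are enforced in the test
suite at `1e-10`:

* all-infinite `δ`: point estimate and SE equal those of the
  corresponding deterministic single-imputation 2×2 analysis;
* no covariate, `δ = 0`: point estimate and SE equal those of the
  complete-case 2×2 analysis (equivalently a complete-case logistic
  regression of `Y` on `Z`, cross-checked against statsmodels).

## Standard errors

Each arm's cell-category counts — (stratum × {observed event, observed
non-event, missing}) — are modelled as a single multinomial draw with the
arm size fixed; arms are independent; `δ` is a constant.  The arm
probability is a smooth function of the counts, and its variance is the
first-order (delta-method) quadratic form in the multinomial covariance,
with an analytic gradient (an internal finite-difference fallback is kept
for testing and must agree to 1e-6).  The effect SE then adds the two arm
variances through `g′(p)²`.

Treating the cell weights as random (multinomial) rather than fixed is a
modelling choice; it is the first-order variance under which the two
exact reductions above hold identically, which is how the contract was
pinned down.  Validation is by simulation (see below): the analytic SE
tracks a 2,000-resample within-arm nonparametric bootstrap and a
Rubin-pooled multiple-imputation SE within 10% at 1,000 participants per
arm, and nominal 95% Wald intervals achieve 92–97% empirical coverage at
500 per arm when the analysis `δ` equals the generative `δ`.

The multiple-imputation oracle performs *proper* imputation: each
completed dataset first draws every cell's responder log-odds from its
asymptotic normal, shifts by `δ`, then draws the missing outcomes, so the
pooled variance reflects uncertainty in the identifiable parameters.
Improper imputation (fixed plug-in probabilities) would understate the
between-imputation variance and could not serve as an SE oracle.

The bootstrap oracle resamples participants within arm.  Since a
participant is fully described by their cell category, this is drawn as a
per-arm multinomial over category counts — identical in distribution —
and every resample is refit through the ordinary `fit` path, keeping the
oracle independent of the analytic variance code.

## Parameters, defaults, degenerate inputs

* `δ` (log IMOR, unitless log odds ratio): no default; the analyst must
  choose, via explicit values, named presets (`mar`, `locf`,
  `missing_equals_event`) scoped to all cells, one arm, or one cell, or
  finite analogues in which `±∞` is replaced by `±log(OR)` for a chosen
  odds ratio (e.g. 2 or 5).  Presets with out-of-scope cells leave them
  *free*, and free slots must be filled explicitly — never defaulted.
* Confidence level: 0.95, normal quantile.
* Boundary observed cells (0% or 100% events among responders) are a hard
  error naming the cell; the optional continuity correction adds 0.5 to
  both outcome counts of the offending cell only.  Silent corrections
  change answers, so the default refuses to guess.
* Cells with no participants carry weight zero and are skipped.  Cells
  with missing participants but no responders are admissible only under
  an infinite `δ` (which fixes their probability); under finite `δ` they
  are an error, since nothing identifies their probability.
* Partially missing `X` is rejected rather than imputed; the model
  assumes the covariate is complete.
* LOCF is undefined without the baseline-outcome covariate and is refused
  for no-covariate models.

## Synthetic data

The generator follows the model's own pattern-mixture factorization
`P(X | Z) · P(R | X, Z) · P(Y | X, Z, R)` with finite `δ`, so generated
data sit exactly in the family the estimator assumes.  Defaults are
anchored to the published treatment-arm margins of the worked-example
internet cessation trial: arm sizes 877/881, P(X = 1) = 0.85, response
probabilities 0.50 (X = 0) and 0.38 (X = 1), treatment responder
log-odds 0.536 and 1.413.  The control arm's cells were not published;
its responder log-odds (0.9, 1.75) were chosen once to give a beneficial
effect of realistic size (log OR ≈ −0.35), and the default `δ` is 0
(MAR).  Seeds are explicit arguments throughout; there is no global
random state.  `generate_trial` retains the full outcome vector alongside
the masked records so tests can verify identification properties (e.g.
that the empirical responder/non-responder logit gap recovers the
generative `δ` at n = 10⁵ per arm).

What the generator does *not* emulate: covariate-dependent dropout
beyond `(X, Z)`, measurement error in `Y`, multi-level or continuous
covariates, longitudinal outcomes, and more than two arms.  Passing
simulation tests therefore demonstrate correctness *within* the model
family, not robustness to misspecification — which is the method's own
framing: the analysis is only as good as the plausibility of the chosen
`δ` range.

## Problem sizes in the validation suite

The routine checks use the sizes at which their Monte-Carlo error makes
the comparison meaningful while the whole suite stays quick: exact
equivalences on 100 random tables; bootstrap (B = 2,000) and MI (m = 100)
SE agreement at 1,000 per arm; coverage over 1,000 replicate trials at
500 per arm; parameter recovery (|bias| < 2 Monte-Carlo SEs) over 500
replicates at 5,000 per arm; replicate-arm variance agreement over 2,000
arms at 800 per arm.

## Known limitations

* The delta-method SE is first-order; in very small cells or with
  near-boundary arm probabilities the Wald interval inherits the usual
  binomial-approximation weaknesses.
* Uncertainty in `δ` itself is deliberately not modelled (it is a
  sensitivity parameter, not an estimate); intervals are conditional on
  the assumption.
* The effect is unadjusted; covariate-adjusted effects under finite `δ`
  are out of scope.
* Two arms only; pairwise comparisons must be run separately for
  multi-arm trials.
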
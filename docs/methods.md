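# Methods

## Model

`mtslm` fits a binary-outcome regression in which the log-odds of success
is a multivariable truncated power spline of degree `m`:

    logit(pi_i) = b0 + sum_j [ sum_{k=1..m} b_jk x_ji^k
                             + sum_{u=1..r_j} c_ju (x_ji - K_ju)_+^m ]

with `(t)_+ = max(t, 0)`.  Each predictor `x_j` carries its own strictly
increasing knot vector `K_j1 < ... < K_jr_j`; knot counts may differ across
predictors.  The response is Bernoulli given the predictors, and
observations are independent.  The expanded design matrix has
`q = 1 + sum_j (m + r_j)` columns: an intercept, then per predictor its
monomial columns and its truncated columns in knot order.  For `m = 1` the
fitted logit is continuous piecewise-linear in each predictor — the model
of interest when the science concerns threshold effects: the local slope of
the log-odds is allowed to change at each knot while the function value
does not jump.

Assumptions worth keeping in mind: the spline is additive across predictors
(no interactions), knots are treated as fixed once chosen (the uncertainty
from knot *selection* is not propagated into the intervals), and predictors
enter on their raw scale, because knot locations are meant to be read in
the units of the data.

## Estimation

The Bernoulli log-likelihood

    L(beta) = sum_i [ y_i X_i'beta - log(1 + exp(X_i'beta)) ]

is globally concave in `beta`.  `newton_raphson_fit` maximizes it with
damped Newton-Raphson: score `X'(y - pi)`, Hessian `-X'WX`,
`W = diag[pi_i(1 - pi_i)]`, update solved with a positive-definite linear
solve (never an explicit inverse), and step-halving (up to 10 halvings)
whenever a full step would decrease the log-likelihood, so the recorded
likelihood trajectory is non-decreasing.  Defaults: start at `beta = 0`
(every fitted probability 1/2), stop when the max-norm of the update falls
below `1e-8`, at most 100 iterations.  The log-sum-exp form
`logaddexp(0, eta)` keeps the likelihood finite for extreme linear
predictors.

Two failure modes are diagnosed rather than papered over.  A rank-deficient
design (for instance a knot outside the observed range, which makes its
truncated column identically zero) raises `SingularInformationError`
before iterating.  (Quasi-)complete separation — iterates diverging past
`|beta| = 1e3`, or no convergence with fitted probabilities pinned within
`1e-10` of 0/1 — raises `SeparationError`, because the Wald intervals
below are meaningless when the MLE does not exist; the practical remedy is
a sparser knot configuration.  Generic IRLS implementations instead return
huge finite coefficients silently in this regime, which is why the error
is loud.

The covariance reported with a converged fit is the inverse Fisher
information `(X'WX)^{-1}` at the optimum; `deviance = -2 L(beta_hat)` and
`AIC = deviance + 2q`.

## Confidence intervals

`Z_j = (b_hat_j - b_j) / SE_hat_j`, with `SE_hat_j` the square root of the
`j`-th diagonal entry of `(X'WX)^{-1}`, is an asymptotically standard
normal pivot (the MLE is consistent and asymptotically normal, and the
plug-in standard error is consistent, so Slutsky applies).  The reported
interval is the Wald interval `b_hat_j -+ z_{alpha/2} SE_hat_j`.  Among all
intervals `[b_hat - d*SE, b_hat - c*SE]` with normal coverage
`Phi(d) - Phi(c) = 1 - alpha`, the shortest is the symmetric one `c = -d`;
`shortest_interval_check` verifies this numerically by minimizing `d - c`
under the coverage constraint (bounded scalar minimization over `c`, with
`d` eliminated through the constraint) and returns a minimizer with
`|c + d| < 1e-6` at any level.

Normal rather than t quantiles are used throughout — the construction is
explicitly asymptotic.  Significance is strict exclusion of zero; an
interval touching zero is non-significant.  No multiplicity adjustment is
applied by default (a Bonferroni flag exists on `interval_table`), matching
the way such per-parameter tables are conventionally reported.

## Knot selection

Given a per-predictor budget `max_knots` (default 4), `search_knots` fits
every knot-count combination in `{1..max_knots}^p` — 64 candidates for
three predictors, 256 for four — and keeps the specification minimizing
AIC.  Knot *locations* for a given count are deterministic:

- `quantile` (default): the `i/(count+1)` empirical quantiles,
  `i = 1..count`;
- `uniform`: equally spaced interior points of the observed range.

Both rules keep knots strictly inside the data.  The quantile rule adapts
to skewed predictors; the uniform rule is provided because grid-like knot
locations are natural on roughly uniform predictors.  Free (continuously
optimized) knot locations are deliberately out of scope.  Ties on AIC break
toward fewer total knots, then enumeration order.  Candidates that fail
(separation, rank deficiency, non-convergence) are recorded with
`converged = False` and excluded from the minimum; the search errs only if
every candidate fails.  `min_knots=0` admits knot-free predictors when
wanted; the default floor of one knot per predictor reflects the model
class's purpose of detecting at least one trend change per predictor.

## Evaluation

Model comparison against plain binary logistic regression (the nested
`m=1, r_j=0` case) uses deviance and AIC on the same fitting data; the
spline model can never have larger deviance than the nested linear-logit
model when both converge, so AIC's `2q` penalty is what arbitrates.
Classification at a probability cutoff (default 0.5; a tie at the cutoff
predicts class 1) yields the confusion matrix, accuracy, sensitivity,
specificity and F1.  AUC is the rank-based Mann-Whitney statistic with
midrank tie handling — identical to the probability that a random positive
outscores a random negative, counting ties one half, which is how it is
unit-tested (exhaustive pair counting).  The VIF screen on the raw
predictors uses the standard definition `VIF_j = 1/(1 - R^2_j)` from an
OLS regression of predictor `j` on the others; values are >= 1 by
construction, with `inf` flagging exact collinearity and 10 the
conventional alarm threshold.  The train/test split (default 80:20,
stratified by response, seeded) is delegated to scikit-learn.

By default the pipeline selects and fits on the training split and scores
classification on the held-out split, while deviance/AIC come from the
training fit; `--no-split` reproduces the alternative full-data workflow.
Which data each published-style metric should use is genuinely ambiguous in
practice, so it is an explicit configuration choice here, not an inference.

## Piecewise interpretation

For a degree-1 fit, the logit contribution of a predictor between
consecutive knots has effective slope `b_1 + c_1 + ... + c_u` (cumulative
sum of the base slope and the knot coefficients activated so far) and
per-unit odds ratio `exp(slope)`.  Segment intercepts are *reconstructed
from continuity* at each knot (`offset_u = offset_{u-1} - c_u K_u`, first
segment offset 0) rather than taken from any externally printed piecewise
constants: the truncated-power representation is continuous by
construction, so the reconstruction is exact, and evaluating the segment
formulas reproduces the design-matrix inner product to 1e-10 (tested).
Higher degrees are rejected: a single per-segment slope does not exist.

## Synthetic data generator

`generate_dataset` draws i.i.d. uniform predictors (unit interval by
default, or per-predictor ranges), builds the truncated-power design for a
*true* specification, and samples `y_i ~ Bernoulli(inv_logit(X_i beta))` —
exactly the process the model assumes.  The default preset
(`sim_study_preset`) emulates a three-predictor simulation study at
n = 200: degree 1; knots at (0.4, 0.8) for x1, (0.5,) for x2 and
(0.2, 0.4, 0.6, 0.8) for x3; slope changes of magnitude 9-24 on the logit
scale, chosen so that the sub-interval trend reversals are plainly visible
in binned empirical-logit plots at that sample size and a straight-line
logit is clearly inadequate, while the linear predictor stays moderate
(sd ~2.1, probabilities within about [0.004, 0.998]) so the MLE remains
finite.  Under this truth the best achievable (true-probability) AUC is
~0.88, and the selected spline model beats plain logistic regression on
AIC across seeds.

What the generator does **not** emulate: correlated or non-uniform
predictors, model misspecification (the fitted family contains the truth),
measurement error, and any spatial or temporal dependence.  Passing tests
therefore certify the estimator and intervals under a correctly specified
additive spline logit — not robustness to violations of it.

`empirical_logit_groups` bins a predictor into equal-width groups and
returns the continuity-corrected empirical logit `log((s+1/2)/(f+1/2))`
per bin (finite even for pure bins; empty bins omitted) — the diagnostic
whose changing local slopes motivate spline modelling in the first place.

`coverage_experiment` is the empirical verification of the pivotal
construction: per replicate it regenerates data from the truth, refits with
the *true* knots, and records whether each level-`1-alpha` interval covers
the true coefficient.  Replicate seeds are spawned from one root seed so a
dropped replicate does not shift the remaining streams; more than 20%
non-convergent replicates invalidates the experiment.

## Numerical choices and problem sizes

- Inverse logit is clamped to the open interval (0,1) at the floating-point
  boundary, so downstream logs never see exactly 0 or 1.
- Matrix solves use `scipy.linalg.solve(..., assume_a="pos")`; only the
  final covariance is materialized as an inverse.
- Monte-Carlo checks in the test suite use 500 replicates at n = 1000 for
  coverage (binomial band [0.93, 0.97] around 0.95), 300 replicates for
  SE calibration (ratio band [0.9, 1.1]), and n up to 1e5 for consistency;
  these sizes put Monte-Carlo noise well below the asserted bands while
  keeping the suite fast.

## Known limitations

- Wald intervals inherit their asymptotic nature.  With the sharp preset
  truth, the knot coefficient supported by the least information
  (`(x3-0.8)+`, active in ~4% of the data at extreme probabilities) covers
  ~92.4% at n = 1000 and re-enters the nominal band by n = 4000.  The
  packaged coverage validation therefore runs at moderate effect sizes
  where n = 1000 is inside the asymptotic regime; for very sharp effects,
  larger samples (or profile-likelihood intervals, out of scope) are
  needed.
- Knot-coefficient estimates converge slowly in absolute terms: truncated
  columns are strongly collinear with the linear term, so their asymptotic
  SEs are ~0.1 even at n = 1e5 for single-knot designs.  Consistency is
  real but paced by that information geometry.
- Intervals condition on the selected knots; selection uncertainty is not
  propagated.
- No penalization, no Firth correction: heavily over-knotted
  specifications on small samples will (correctly) fail with separation
  errors rather than return shrunken estimates.
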
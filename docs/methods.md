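# Methods

## The problem

A semicontinuous longitudinal outcome `Y_ij >= 0` (subject `i`, visit `j`)
mixes an exact point mass at zero with a continuous, typically right-skewed
positive distribution.  Treating such data with a single continuous model
ignores that zeros and positives may be driven by different processes;
modelling only the positives discards the information in the zeros and
yields effects that are conditional on `Y > 0` rather than effects on the
population mean.  This package implements the marginalized two-part (mTP)
mixed model, which keeps the two-process structure but parameterizes the
*overall* marginal mean directly, together with three comparators
(conditional two-part with uncorrelated or correlated random intercepts,
and a one-part model).

## Generalized gamma family

The continuous component is the three-parameter generalized gamma (GG)
density with shape `k` (any sign), scale `sigma > 0` and log-scale location
`mu`.  With `eta = |k|^-2` and `u = sign(k)(log y - mu)/sigma`,

    f(y) = eta^eta / (sigma y Gamma(eta) sqrt(eta)) * exp(u sqrt(eta) - eta e^{|k| u}).

Raw moments are `E(Y^s) = exp{s mu + s sigma log(k^2)/k
+ logGamma(eta + s sigma/k) - logGamma(eta)}`, existing iff
`eta + s sigma / k > 0`; the mean is `E(Y) = exp(mu + C)` with the offset

    C(sigma, k) = sigma log(k^2)/k + logGamma(eta + sigma/k) - logGamma(eta).

Special cases: `sigma = k` is a gamma with mean `e^mu` (`C = 0`); `k = 1` is
Weibull (`C = logGamma(1 + sigma)`); `k -> 0` is lognormal (`C = sigma^2/2`).
The variance is computed as `E(Y^2) - E(Y)^2` from the moment formula; both
the moment expression and this variance identity are validated against
numerical quadrature of the density in the test suite, because closed-form
variants circulating in the literature are not always dimensionally
consistent.

Numerics: all Gamma-function arithmetic is via `gammaln`; densities are
computed and returned in log space; `|k| <= 1e-4` switches to the analytic
lognormal limit (below this the direct formula cancels catastrophically —
the switch is inclusive because at `|k| = 1e-4` the genuine GG-lognormal gap
is already ~5e-4 in log density, and continuity across the switch is
tested).  Sampling uses the gamma transform
`y = exp(mu + (sigma/k) log(k^2 g))`, `g ~ Gamma(eta, 1)`.

## Model families

All families share a logistic binary part `pi_ij = expit(z'_ij alpha + u_1i)`
for `P(Y > 0)` — a *positive* `alpha` coefficient means higher odds of a
non-zero — and a GG continuous part. `(u_1i, u_2i) ~ BVN(0, G)`.

* `tp_uncorrelated`: `mu_ij = x'_ij delta + u_2i`, `G` diagonal; the parts
  share no parameters, so they are fit as two independent one-dimensional
  problems and reported jointly.
* `tp_correlated`: same conditional location, free covariance in `G`,
  estimated jointly by a 2-D integral per subject.
* `mtp`: `mu_ij = x'_ij beta + u_2i - log(pi_ij) - C(sigma, k)`, which makes
  `pi_ij E(Y_ij | Y_ij > 0, u) = exp(x'_ij beta + u_2i)` hold exactly:
  `beta` acts on the marginal mean with zeros included.  The identity is a
  machine-precision property test.
* `one_part`: GG mixed model for all records, `mu_ij = w'_ij gamma + b_0i`;
  zeros are replaced by a constant `c`, by default half the smallest
  positive outcome (logged and configurable — no detection limit is assumed
  by the package).

A configurable `zero_threshold` (default exactly 0) decides what counts as
a zero, since "negligible" assay values are a common source of the point
mass.

## Estimation

The marginal likelihood integrates each subject's conditional likelihood
over its random intercepts.  Integration is adaptive Gauss–Hermite: a
damped Newton search with analytic gradient/Hessian of the log integrand
(the GG log-density derivative w.r.t. `mu` is `(e^{k w} - 1)/(k sigma)` with
`w = (log y - mu)/sigma`, which keeps the search cheap and exact) finds the
posterior mode per subject; the tensor-product Hermite rule (default 7
nodes/dimension, 49 points in 2-D) is recentered there and rescaled by the
curvature.  With all random-effect variances zero the marginal reduces
exactly to the integrand at `u = 0`.  Accuracy is tested against brute-force
2-D trapezoid integration (relative error < 1e-4 at 7 nodes) and for
stability in the node count (7 vs 15 nodes < 1e-5 relative).

Maximization is BFGS on an unconstrained scale: `log sigma` (and `log k`
for the gamma case, raw `k` for the full GG), `log` random-effect SDs and
`atanh` correlation, so `G` is positive definite by construction.  Starting
values are stage-wise: a plain logistic GLM for `alpha`, a log-link gamma
GLM on the positives for `delta`/`beta`, variances 0.25, correlation 0; the
mTP fit warm-starts from a `tp_correlated` solution when one is available
(or runs a cheap internal pre-fit).  Convergence requires the BFGS gradient
norm below `1e-4`, or below the finite-difference noise floor of the
objective (`2e-6 |f|`) when the line search has stalled there;
non-convergence is reported in the result, never silently.  The
mode-search tolerance is deliberately tight (1e-8) so that warm-started
mode caching cannot make the objective noisy at finite-difference scale.

Standard errors: central finite-difference Hessian of the negative log
likelihood at the optimum (per-parameter scaled steps), inverted to the
covariance and mapped to the natural scale (variances, covariance, sigma,
k) by a delta-method Jacobian.  An indefinite information matrix — typical
of variance estimates at the boundary — flags the fit and yields NaN SEs
rather than fabricated ones.  Wald z-tests provide the reported p-values.
AIC is `-2 logLik + 2p`; BIC uses the number of *subjects* (independent
units) as its sample size, which is also the convention that reproduces the
published fit-statistic arithmetic this package's tests check.

Empirical-Bayes random-effect predictions are the per-subject posterior
modes at the MLE (the adaptive-quadrature centering points); they shrink
toward zero as a subject contributes fewer records.

## Simulation world

`default_study_config` states the package's simulation world once: one
binary (Bernoulli 0.5) and one standard-normal covariate in each part,
moderate effects (`|coef| = 0.5`), gamma continuous part with
`k = sigma = 0.5`, random-intercept variances 0.5 with correlation 0.5, and
a binary-part intercept calibrated by root finding (Gauss–Hermite over
`u_1`, Monte Carlo over covariates) to hit the target zero proportion (30%
or 50% in the replicate studies; the calibration itself is verified by
simulation to within one percentage point).  Replicate seeds derive from
the master seed by the counter scheme `default_rng([seed, r])`.

What the generator emulates: the mixed zero/positive structure, within-
subject correlation through correlated intercepts, covariate-driven zero
probability and marginal mean.  What it does not: serial correlation beyond
the intercepts, covariate correlation across parts, missing visits,
detection-limit censoring, or covariate measurement error.  A green
recovery/coverage test therefore establishes internal consistency of the
simulator + estimator pair under the stated world, not robustness to those
real-data features.

One consequence worth stating: under mTP truth the marginal mean is
*exactly* log-linear in the covariates, so the one-part model's mean
structure is correctly specified there and its slope estimates are nearly
unbiased — its deficiencies in that world are distributional (a point mass
replaced by a constant inside a GG density), which inflates variance and
distorts the distributional parameters rather than the slopes.  The
replicate-study tests accordingly assert strictly only that mTP dominates
all comparators on aggregate |bias| and MSE of the marginal-mean
coefficients, and treat the ordering among the misspecified comparators as
a soft check.  The large conditional-versus-marginal intercept bias of the
two-part fits is the textbook marginalization effect and dominates their
aggregate error.

## Design choices and limitations

* Random intercepts only; no random slopes, non-normal random effects, or
  covariate-dependent `sigma`/`k`.
* Analytic gradients of the *outer* likelihood are not implemented; BFGS
  uses finite differences.  This is the main cost driver; the per-subject
  mode search is analytic.
* `tp_uncorrelated` standard errors come from the two separate information
  matrices (block-diagonal), consistent with its separate-fit definition.
* Complete-case ingestion: rows with missing values in used columns are
  dropped and counted; no imputation.
* The bias/MSE driver excludes non-converged replicates and reports the
  count — at the default tolerances non-convergence is rare (< 5%) in the
  stated world.
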
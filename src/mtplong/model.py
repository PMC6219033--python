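"""Data model and likelihood building blocks for longitudinal semicontinuous panels.

A semicontinuous outcome mixes an exact point mass at zero with a continuous
positive distribution.  Four model families are supported:

``one_part``
    A single generalized-gamma (GG) mixed model for all values, zeros
    replaced by a small constant; random intercept ``b0``.
``tp_uncorrelated``
    Two-part model: logistic for P(Y > 0) with random intercept ``b1``, GG
    for Y | Y > 0 with random intercept ``b2``; the two parts independent
    and fit separately.
``tp_correlated``
    Same two parts, but ``(b1, b2)`` bivariate normal with free covariance,
    estimated jointly.
``mtp``
    Marginalized two-part model: the same binary part, but the continuous
    part is re-parameterized so its coefficients beta act multiplicatively
    on the *overall* marginal mean E(Y) = exp(x'beta + u2) — zeros
    included — via the induced GG location
    mu = x'beta + u2 - log(pi) - C(sigma, k).

Everything here is per-observation / per-subject and free of quadrature;
marginal likelihood evaluation and fitting live in :mod:`mtplong.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .ggfamily import GGParams, _gg_logpdf_raw, offset_C

__all__ = [
    "FAMILIES",
    "DISTRIBUTIONS",
    "PanelDataset",
    "RandomEffectsCov",
    "ModelSpec",
    "ParameterVector",
    "classify_zero",
    "zero_part_prob",
    "tp_conditional_location",
    "mtp_location",
    "tp_marginal_mean",
    "one_part_location",
    "subject_log_integrand",
    "subject_integrand",
    "log_expit",
]

FAMILIES = ("one_part", "tp_uncorrelated", "tp_correlated", "mtp")
DISTRIBUTIONS = ("gg", "gamma", "weibull", "lognormal")


def log_expit(x):
    """log(expit(x)), stable for large |x| (down to x ~ -745)."""
    x = np.asarray(x, dtype=float)
    return -np.logaddexp(0.0, -x)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class PanelDataset:
    """Long-format repeated-measures data, one row per subject-visit.

    Records are stored sorted by subject (order of first appearance), so each
    subject occupies a contiguous block ``starts[i]:starts[i+1]``.

    Parameters
    ----------
    subject : array-like, shape (N,)
        Subject identifier per record (any hashable labels).
    time : array-like, shape (N,)
        Visit time.
    y : array-like, shape (N,)
        Non-negative outcome with a point mass at zero.
    Z : ndarray, shape (N, p_z)
        Covariates for the binary ("zero") part, intercept column included.
    X : ndarray, shape (N, p_x)
        Covariates for the continuous part, intercept included.
    W : ndarray, shape (N, p_w), optional
        Covariates for the one-part model; defaults to ``X``.
    """

    def __init__(self, subject, time, y, Z, X, W=None):
        subject = np.asarray(subject)
        y = np.asarray(y, dtype=float)
        time = np.asarray(time, dtype=float)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        N = len(y)
        if not (len(subject) == len(time) == Z.shape[0] == X.shape[0] == N):
            raise ValueError("subject, time, y, Z, X must have equal length")
        if N == 0:
            raise ValueError("empty dataset")
        bad = ~np.isfinite(y) | (y < 0)
        if np.any(bad):
            raise ValueError(
                f"outcome must be finite and >= 0; offending record index {np.flatnonzero(bad)[0]}"
            )
        for name, M in (("Z", Z), ("X", X)):
            if not np.all(np.isfinite(M)):
                idx = np.flatnonzero(~np.isfinite(M).all(axis=1))[0]
                raise ValueError(f"non-finite covariate in {name} at record {idx}")

        # stable sort: subjects in order of first appearance, rows kept in order
        labels, first = np.unique(subject, return_index=True)
        labels = labels[np.argsort(first)]
        label_to_pos = {lab: i for i, lab in enumerate(labels)}
        subj_index = np.fromiter((label_to_pos[s] for s in subject), int, N)
        order = np.argsort(subj_index, kind="stable")

        self.subject_ids = labels
        self.subj_index = subj_index[order]
        self.y = y[order]
        self.time = time[order]
        self.Z = Z[order]
        self.X = X[order]
        if W is None:
            self.W = self.X
        else:
            W = np.atleast_2d(np.asarray(W, dtype=float))
            if W.shape[0] != N or not np.all(np.isfinite(W)):
                raise ValueError("W must be finite with one row per record")
            self.W = W[order]
        counts = np.bincount(self.subj_index, minlength=len(labels))
        self.starts = np.concatenate([[0], np.cumsum(counts)])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_records(self) -> int:
        return len(self.y)

    def subject_slice(self, i: int) -> slice:
        return slice(self.starts[i], self.starts[i + 1])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PanelDataset(n_subjects={self.n_subjects}, n_records={self.n_records}, "
            f"p_z={self.Z.shape[1]}, p_x={self.X.shape[1]}, p_w={self.W.shape[1]})"
        )


@dataclass
class RandomEffectsCov:
    """Covariance of the (binary-part, continuous-part) random intercepts.

    ``correlated=False`` forces ``cov12 = 0``; the one-part family uses only
    the ``var2`` slot (housing the variance of its single intercept ``b0``
    alongside the continuous-part path).
    """

    var1: float = 0.0
    var2: float = 0.0
    cov12: float = 0.0
    correlated: bool = True

    def __post_init__(self) -> None:
        if self.var1 < 0 or self.var2 < 0:
            raise ValueError("random-effect variances must be non-negative")
        if not self.correlated:
            self.cov12 = 0.0
        bound = np.sqrt(self.var1 * self.var2)
        if abs(self.cov12) > bound * (1 + 1e-10) + 1e-300:
            raise ValueError("cov12 implies |correlation| > 1")

    @property
    def corr(self) -> float:
        denom = np.sqrt(self.var1 * self.var2)
        return 0.0 if denom == 0 else float(self.cov12 / denom)

    def matrix(self) -> np.ndarray:
        return np.array([[self.var1, self.cov12], [self.cov12, self.var2]])


@dataclass
class ModelSpec:
    """Which family / continuous distribution to use and what counts as a zero.

    The distribution constrains the GG shape/scale: ``gamma`` ties
    ``sigma == k`` (one free parameter), ``weibull`` fixes ``k = 1``,
    ``lognormal`` is the ``k -> 0`` limit, ``gg`` leaves both free.
    ``roles`` optionally records covariate names per part for reporting.
    """

    family: str
    distribution: str = "gamma"
    zero_threshold: float = 0.0
    roles: dict | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; choose from {DISTRIBUTIONS}"
            )
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be >= 0")


@dataclass
class ParameterVector:
    """Full parameter set of one model.

    ``alpha`` are the binary-part coefficients (absent for one_part);
    ``cont_coef`` are beta (mtp), delta (two-part) or gamma (one-part);
    ``k``/``sigma`` the GG shape/scale (already satisfying the distribution
    constraint, with ``k = 0`` denoting the lognormal limit); ``re_cov`` the
    random-intercept covariance.
    """

    cont_coef: np.ndarray
    k: float
    sigma: float
    re_cov: RandomEffectsCov
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cont_coef = np.asarray(self.cont_coef, dtype=float)
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)

    def gg_params(self, mu: float = 0.0) -> GGParams:
        return GGParams(k=self.k, sigma=self.sigma, mu=mu)

    def n_free_params(self, spec: ModelSpec) -> int:
        """Number of free parameters (drives AIC/BIC)."""
        p = len(self.cont_coef)
        if spec.family != "one_part":
            p += len(self.alpha)
        p += {"gg": 2, "gamma": 1, "weibull": 1, "lognormal": 1}[spec.distribution]
        if spec.family == "one_part":
            p += 1  # var of b0
        elif spec.family == "tp_uncorrelated":
            p += 2  # var1, var2
        else:
            p += 3  # var1, var2, cov12
        return p


# ---------------------------------------------------------------------------
# per-observation pieces
# ---------------------------------------------------------------------------


def classify_zero(y, spec: ModelSpec):
    """Indicator of a NON-zero outcome: 1 if ``y > zero_threshold`` else 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("outcome must be non-negative")
    return (y > spec.zero_threshold).astype(int)


def zero_part_prob(z, alpha, u1: float):
    """P(Y > 0) = expit(z'alpha + u1); stable for |linear predictor| <= 700."""
    z = np.asarray(z, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if z.shape[-1] != alpha.shape[0]:
        raise ValueError("z and alpha dimensions disagree")
    return expit(z @ alpha + u1)


def tp_conditional_location(x, delta, u2: float):
    """Conditional (on Y>0) GG location of a two-part model: x'delta + u2."""
    x = np.asarray(x, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if x.shape[-1] != delta.shape[0]:
        raise ValueError("x and delta dimensions disagree")
    return x @ delta + u2


def mtp_location(x, beta, u2: float, pi, C: float):
    """Induced GG location of the marginalized two-part model.

    ``mu = x'beta + u2 - log(pi) - C`` so that
    ``pi * exp(mu + C) == exp(x'beta + u2)`` holds exactly: the marginal
    mean of Y, zeros included, is ``exp(x'beta + u2)``.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] != beta.shape[0]:
        raise ValueError("x and beta dimensions disagree")
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("pi must lie in (0, 1]")
    return x @ beta + u2 - np.log(pi) - C


def tp_marginal_mean(pi, mu, C: float):
    """Marginal mean of a two-part model: E(Y) = pi * exp(mu + C)."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    return pi * np.exp(np.asarray(mu, dtype=float) + C)


def one_part_location(w, gamma, u0: float):
    """One-part GG location: w'gamma + u0 (applied to all records)."""
    w = np.asarray(w, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if w.shape[-1] != gamma.shape[0]:
        raise ValueError("w and gamma dimensions disagree")
    return w @ gamma + u0


# ---------------------------------------------------------------------------
# per-subject conditional likelihood
# ---------------------------------------------------------------------------


def subject_log_integrand(y, Z, X, params: ParameterVector, spec: ModelSpec, u):
    """Log conditional likelihood of one subject's records given ``u = (u1, u2)``.

    For the two joint families:

        sum_j [ I(y_j = 0) * log(1 - pi_j)
                + I(y_j > 0) * (log pi_j + log f(y_j; mu_j, sigma, k)) ]

    with ``pi_j = expit(z_j'alpha + u1)`` and ``mu_j`` from
    :func:`tp_conditional_location` (tp_correlated) or :func:`mtp_location`
    (mtp).  Computed in log space throughout.
    """
    if spec.family not in ("tp_correlated", "mtp"):
        raise ValueError("subject_log_integrand requires a joint two-part family")
    u1, u2 = float(u[0]), float(u[1])
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    nz = classify_zero(y, spec).astype(bool)
    lp = Z @ params.alpha + u1
    log_pi = log_expit(lp)
    log_1mpi = log_expit(-lp)
    total = float(np.sum(log_1mpi[~nz]))
    if np.any(nz):
        if spec.family == "mtp":
            C = offset_C(params.sigma, params.k)
            mu = X[nz] @ params.cont_coef + u2 - log_pi[nz] - C
        else:
            mu = X[nz] @ params.cont_coef + u2
        total += float(np.sum(log_pi[nz]))
        total += float(
            np.sum(_gg_logpdf_raw(np.log(y[nz]), mu, params.sigma, params.k))
        )
    return total


def subject_integrand(y, Z, X, params: ParameterVector, spec: ModelSpec, u) -> float:
    """Conditional likelihood (natural scale) of one subject given ``u``."""
    return float(np.exp(subject_log_integrand(y, Z, X, params, spec, u)))
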
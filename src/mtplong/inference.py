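"""Maximum-likelihood estimation for the four panel families.

The marginal likelihood integrates the per-subject conditional likelihood
over the random intercepts — a 2-D integral for the joint families
(``tp_correlated``, ``mtp``), 1-D per part otherwise.  Integration uses
adaptive Gauss-Hermite quadrature: per subject, a damped Newton search (with
analytic gradients/Hessians of the log integrand) locates the posterior mode
of the random effects, and the tensor-product Hermite rule is recentered and
rescaled there.  Maximization is quasi-Newton (BFGS) on an unconstrained
parameterization: log scales/SDs, atanh correlation, so the random-effect
covariance is positive semidefinite by construction.

Standard errors come from the observed information (central finite-difference
Hessian at the optimum), mapped to the natural scale by the delta method.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .ggfamily import LOGNORMAL_K_THRESHOLD, offset_C, _gg_logpdf_raw
from .model import (
    ModelSpec,
    PanelDataset,
    ParameterVector,
    RandomEffectsCov,
    classify_zero,
    log_expit,
)

__all__ = [
    "QuadratureConfig",
    "FitOptions",
    "FitResult",
    "marginal_subject_loglik",
    "total_negloglik",
    "fit_model",
    "compute_standard_errors",
    "predict_random_effects",
    "information_criteria",
    "fd_hessian",
]

_SD_TOL = 1e-8  # random-effect SD below this is treated as exactly zero


@dataclass
class QuadratureConfig:
    """Gauss-Hermite settings.

    ``nodes_per_dim`` Hermite nodes per random-effect dimension (tensor
    product in 2-D).  With ``adaptive`` the rule is recentered at each
    subject's posterior mode and rescaled by the curvature there; otherwise
    it is centered at the prior (mean 0, covariance G).
    """

    nodes_per_dim: int = 7
    adaptive: bool = True
    # tight enough that the centering is independent of its warm start;
    # a looser tolerance makes the likelihood surface noisy at FD-gradient scale
    mode_search_tolerance: float = 1e-8
    max_mode_iter: int = 40

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 1:
            raise ValueError("nodes_per_dim must be >= 1")


@dataclass
class FitOptions:
    maxiter: int = 500
    gtol: float = 1e-4
    #: for mtp: warm-start from a tp_correlated pre-fit (stage-wise start otherwise)
    pre_fit: bool = True
    #: one-part replacement for zeros; default half the smallest positive outcome
    zero_constant: float | None = None
    #: skip the finite-difference Hessian (SEs reported as NaN); used by
    #: replicate studies where only point estimates are summarized
    compute_se: bool = True


@dataclass
class FitResult:
    """Maximum-likelihood fit of one family."""

    estimates: ParameterVector
    spec: ModelSpec
    param_names: list
    theta: np.ndarray          # free parameters, unconstrained scale
    natural: np.ndarray        # same parameters on the natural scale
    se: np.ndarray             # natural-scale standard errors (NaN if undefined)
    vcov: np.ndarray           # natural-scale covariance of the estimates
    loglik: float
    n_params: int
    n_subjects: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    gradient_norm: float
    eb_effects: np.ndarray     # (n_subjects, 2) posterior modes (u1, u2)
    messages: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def neg2loglik(self) -> float:
        return -2.0 * self.loglik

    def wald_pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.natural / self.se
        return 2.0 * norm.sf(np.abs(z))


def information_criteria(loglik: float, n_params: int, n_subjects: int):
    """(AIC, BIC, -2 logLik); BIC sample size = number of subjects."""
    if n_params < 0 or n_subjects < 1:
        raise ValueError("need n_params >= 0 and n_subjects >= 1")
    neg2 = -2.0 * loglik
    return neg2 + 2.0 * n_params, neg2 + n_params * np.log(n_subjects), neg2


# ---------------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------------

_DIST_BLOCK = {"gg": 2, "gamma": 1, "weibull": 1, "lognormal": 1}


class _Transform:
    """Maps the free vector theta to model parameters and back.

    Layouts (theta order):
      joint:    alpha | coef | dist | log sd1, log sd2, atanh rho
      binary:   alpha | log sd1
      cont:     coef | dist | log sd2
      one_part: coef | dist | log sd0
    where dist is [k, log sigma] for gg, [log k] for gamma (sigma = k),
    [log sigma] for weibull (k = 1) and lognormal (k = 0).
    """

    def __init__(self, kind: str, distribution: str, p_alpha: int, p_coef: int):
        self.kind = kind
        self.distribution = distribution
        self.p_alpha = p_alpha if kind in ("joint", "binary") else 0
        self.p_coef = p_coef if kind != "binary" else 0
        self.has_dist = kind != "binary"
        n = self.p_alpha + self.p_coef
        if self.has_dist:
            n += _DIST_BLOCK[distribution]
        n += {"joint": 3, "binary": 1, "cont": 1, "one_part": 1}[kind]
        self.n_free = n

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        if len(theta) != self.n_free:
            raise ValueError(f"expected {self.n_free} free parameters, got {len(theta)}")
        i = 0
        alpha = theta[: self.p_alpha] if self.p_alpha else None
        i += self.p_alpha
        coef = theta[i : i + self.p_coef]
        i += self.p_coef
        k, sigma = 1.0, 1.0
        if self.has_dist:
            d = self.distribution
            if d == "gg":
                k = theta[i]
                sigma = np.exp(theta[i + 1])
                i += 2
            elif d == "gamma":
                k = sigma = np.exp(theta[i])
                i += 1
            elif d == "weibull":
                k, sigma = 1.0, np.exp(theta[i])
                i += 1
            else:  # lognormal
                k, sigma = 0.0, np.exp(theta[i])
                i += 1
        if self.kind == "joint":
            sd1, sd2 = np.exp(theta[i]), np.exp(theta[i + 1])
            rho = np.tanh(theta[i + 2])
            re = RandomEffectsCov(sd1**2, sd2**2, rho * sd1 * sd2, correlated=True)
        elif self.kind == "binary":
            re = RandomEffectsCov(np.exp(theta[i]) ** 2, 0.0, 0.0, correlated=False)
        else:  # cont / one_part: single intercept housed in var2
            re = RandomEffectsCov(0.0, np.exp(theta[i]) ** 2, 0.0, correlated=False)
        return ParameterVector(cont_coef=coef, k=float(k), sigma=float(sigma), re_cov=re, alpha=alpha)

    def pack(self, pv: ParameterVector):
        parts = []
        if self.p_alpha:
            parts.append(np.asarray(pv.alpha, dtype=float))
        if self.p_coef:
            parts.append(np.asarray(pv.cont_coef, dtype=float))
        if self.has_dist:
            d = self.distribution
            if d == "gg":
                parts.append([pv.k, np.log(pv.sigma)])
            elif d == "gamma":
                parts.append([np.log(pv.k)])
            else:
                parts.append([np.log(pv.sigma)])
        re = pv.re_cov
        if self.kind == "joint":
            sd1, sd2 = np.sqrt(re.var1), np.sqrt(re.var2)
            parts.append([np.log(max(sd1, 1e-4)), np.log(max(sd2, 1e-4)),
                          np.arctanh(np.clip(re.corr, -0.999, 0.999))])
        elif self.kind == "binary":
            parts.append([np.log(max(np.sqrt(re.var1), 1e-4))])
        else:
            parts.append([np.log(max(np.sqrt(re.var2), 1e-4))])
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def natural_names(self, alpha_names=None, coef_names=None):
        names = []
        if self.p_alpha:
            names += list(alpha_names) if alpha_names is not None else [
                f"alpha[{j}]" for j in range(self.p_alpha)
            ]
        if self.p_coef:
            names += list(coef_names) if coef_names is not None else [
                f"coef[{j}]" for j in range(self.p_coef)
            ]
        if self.has_dist:
            names += {"gg": ["k", "sigma"], "gamma": ["sigma"],
                      "weibull": ["sigma"], "lognormal": ["sigma"]}[self.distribution]
        names += {"joint": ["var1", "var2", "cov12"], "binary": ["var1"],
                  "cont": ["var2"], "one_part": ["var0"]}[self.kind]
        return names

    def natural(self, theta):
        """Natural-scale parameter vector matching :meth:`natural_names`."""
        pv = self.unpack(theta)
        out = []
        if self.p_alpha:
            out.append(pv.alpha)
        if self.p_coef:
            out.append(pv.cont_coef)
        if self.has_dist:
            if self.distribution == "gg":
                out.append([pv.k, pv.sigma])
            else:
                out.append([pv.sigma])
        re = pv.re_cov
        if self.kind == "joint":
            out.append([re.var1, re.var2, re.cov12])
        elif self.kind == "binary":
            out.append([re.var1])
        else:
            out.append([re.var2])
        return np.concatenate([np.atleast_1d(np.asarray(o, dtype=float)) for o in out])


def _transform_for(spec: ModelSpec, p_z: int, p_x: int, kind: str | None = None) -> _Transform:
    if kind is None:
        kind = {"mtp": "joint", "tp_correlated": "joint", "one_part": "one_part"}.get(spec.family)
        if kind is None:
            raise ValueError("tp_uncorrelated uses two components; pass kind explicitly")
    return _Transform(kind, spec.distribution, p_z, p_x)


# ---------------------------------------------------------------------------
# conditional likelihood components
# ---------------------------------------------------------------------------


class _Component:
    """Vectorized conditional likelihood of one random-effect component.

    ``kind``: 'joint' (binary + continuous, 2-D random effect), 'binary'
    (logistic, 1-D), or 'cont' (GG on a record subset, 1-D).  All methods
    take per-subject random-effect arrays and return per-subject sums.
    """

    def __init__(self, kind, dataset: PanelDataset, spec: ModelSpec, *,
                 use_w=False, y_override=None, positives_only=False):
        self.kind = kind
        self.spec = spec
        self.n = dataset.n_subjects
        self.dim = 2 if kind == "joint" else 1
        y = dataset.y if y_override is None else np.asarray(y_override, dtype=float)
        nz = classify_zero(y, spec).astype(bool)
        Xmat = dataset.W if use_w else dataset.X
        if kind == "cont" and positives_only:
            keep = nz
        else:
            keep = np.ones(len(y), dtype=bool)
        self.subj_index = dataset.subj_index[keep]
        self.counts = np.bincount(self.subj_index, minlength=self.n)
        self.starts = np.concatenate([[0], np.cumsum(self.counts)])
        self.nz = nz[keep]
        self.y = y[keep]
        with np.errstate(divide="ignore"):
            self.logy = np.where(self.nz, np.log(np.maximum(self.y, 1e-300)), 0.0)
        self.Z = dataset.Z[keep] if kind in ("joint", "binary") else None
        self.X = Xmat[keep] if kind in ("joint", "cont") else None
        if kind == "cont" and np.any(~self.nz):
            raise ValueError("continuous component requires strictly positive outcomes")

    # -- linear predictors -------------------------------------------------
    def _lin(self, pv: ParameterVector):
        a = self.Z @ pv.alpha if self.Z is not None else None
        b = self.X @ pv.cont_coef if self.X is not None else None
        return a, b

    @staticmethod
    def _gg_l1_l2(w, sigma, k):
        """First/second derivative of the GG log-density w.r.t. mu."""
        if abs(k) <= LOGNORMAL_K_THRESHOLD:
            return w / sigma, np.full_like(w, -1.0 / sigma**2)
        with np.errstate(over="ignore"):
            E = np.exp(np.minimum(k * w, 600.0))
        return (E - 1.0) / (k * sigma), -E / sigma**2

    def _sum_subjects(self, rec_vals):
        """Sum record-level values (n_rec, ...) into per-subject (n, ...)."""
        if len(rec_vals) == 0:
            shape = (self.n,) + rec_vals.shape[1:]
            return np.zeros(shape)
        out = np.add.reduceat(rec_vals, self.starts[:-1], axis=0)
        out[self.counts == 0] = 0.0
        return out

    def cond_loglik(self, pv: ParameterVector, U):
        """Per-subject log conditional likelihood at nodes U of shape (n, Q, d)."""
        U = np.asarray(U, dtype=float)
        a, b = self._lin(pv)
        sigma, k = pv.sigma, pv.k
        if self.kind == "binary":
            lp = a[:, None] + U[self.subj_index, :, 0]
            contrib = np.where(self.nz[:, None], log_expit(lp), log_expit(-lp))
            return self._sum_subjects(contrib)
        if self.kind == "cont":
            mu = b[:, None] + U[self.subj_index, :, 0]
            return self._sum_subjects(_gg_logpdf_raw(self.logy[:, None], mu, sigma, k))
        # joint; log(1 - pi) = log(pi) - lp saves one transcendental pass
        lp = a[:, None] + U[self.subj_index, :, 0]
        log_pi = log_expit(lp)
        contrib = log_pi - np.where(self.nz[:, None], 0.0, lp)
        pos = self.nz
        if np.any(pos):
            u2 = U[self.subj_index, :, 1][pos]
            mu = b[pos, None] + u2
            if self.spec.family == "mtp":
                C = offset_C(sigma, k)
                mu = mu - log_pi[pos] - C
            contrib[pos] += _gg_logpdf_raw(self.logy[pos, None], mu, sigma, k)
        return self._sum_subjects(contrib)

    def cond_grad_hess(self, pv: ParameterVector, u):
        """Gradient (n, d) and Hessian (n, d, d) of the log integrand at u (n, d)."""
        a, b = self._lin(pv)
        sigma, k = pv.sigma, pv.k
        n, d = self.n, self.dim
        if self.kind == "binary":
            lp = a + u[self.subj_index, 0]
            pi = expit(lp)
            g = self._sum_subjects(self.nz.astype(float) - pi)
            h = self._sum_subjects(-pi * (1.0 - pi))
            return g.reshape(n, 1), h.reshape(n, 1, 1)
        if self.kind == "cont":
            mu = b + u[self.subj_index, 0]
            w = (self.logy - mu) / sigma
            l1, l2 = self._gg_l1_l2(w, sigma, k)
            g = self._sum_subjects(l1)
            h = self._sum_subjects(l2)
            return g.reshape(n, 1), h.reshape(n, 1, 1)
        # joint
        lp = a + u[self.subj_index, 0]
        pi = expit(lp)
        nzf = self.nz.astype(float)
        g1 = nzf - pi
        h11 = -pi * (1.0 - pi)
        g2 = np.zeros_like(g1)
        h12 = np.zeros_like(g1)
        h22 = np.zeros_like(g1)
        pos = self.nz
        if np.any(pos):
            mu = b[pos] + u[self.subj_index, 1][pos]
            pip = pi[pos]
            if self.spec.family == "mtp":
                C = offset_C(sigma, k)
                mu = mu - log_expit(lp[pos]) - C
            w = (self.logy[pos] - mu) / sigma
            l1, l2 = self._gg_l1_l2(w, sigma, k)
            g2[pos] = l1
            h22[pos] = l2
            if self.spec.family == "mtp":
                one_m = 1.0 - pip
                g1[pos] += -l1 * one_m
                h11[pos] += l2 * one_m**2 + l1 * pip * one_m
                h12[pos] = -l2 * one_m
        G = np.stack([self._sum_subjects(g1), self._sum_subjects(g2)], axis=1)
        H = np.empty((n, 2, 2))
        H[:, 0, 0] = self._sum_subjects(h11)
        H[:, 0, 1] = H[:, 1, 0] = self._sum_subjects(h12)
        H[:, 1, 1] = self._sum_subjects(h22)
        return G, H


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite marginal likelihood
# ---------------------------------------------------------------------------


def _hermite_nodes(q: int, d: int):
    t, w = np.polynomial.hermite.hermgauss(q)
    if d == 1:
        T = t.reshape(-1, 1)
        logw = np.log(w)
    else:
        ta, tb = np.meshgrid(t, t, indexing="ij")
        T = np.column_stack([ta.ravel(), tb.ravel()])
        wa, wb = np.meshgrid(w, w, indexing="ij")
        logw = np.log((wa * wb).ravel())
    return T, logw, np.sum(T * T, axis=1)


def _search_modes(comp: _Component, pv, act, Ginv_act, quad, u0=None):
    """Damped Newton search for per-subject posterior modes (active dims)."""
    n, d = comp.n, comp.dim
    u = np.zeros((n, d)) if u0 is None else np.array(u0, dtype=float)
    d_act = int(act.sum())
    idx = np.flatnonzero(act)

    def objective(uu):
        ll = comp.cond_loglik(pv, uu[:, None, :])[:, 0]
        ua = uu[:, idx]
        return ll - 0.5 * np.einsum("ni,ij,nj->n", ua, Ginv_act, ua)

    obj = objective(u)
    ok = True
    for _ in range(quad.max_mode_iter):
        g, H = comp.cond_grad_hess(pv, u)
        ga = g[:, idx] - u[:, idx] @ Ginv_act
        Ha = H[np.ix_(np.arange(n), idx, idx)] - Ginv_act
        if np.max(np.abs(ga)) < quad.mode_search_tolerance:
            break
        # Newton direction on -Ha (which should be PD); fall back to scaled
        # gradient where curvature is not usable
        if d_act == 1:
            h = -Ha[:, 0, 0]
            good = h > 0
            step = np.where(good, ga[:, 0] / np.where(good, h, 1.0),
                            np.clip(ga[:, 0], -1.0, 1.0))
            steps = step[:, None]
        else:
            M = -Ha
            det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] ** 2
            good = (M[:, 0, 0] > 0) & (det > 0)
            dsafe = np.where(good, det, 1.0)
            s0 = (M[:, 1, 1] * ga[:, 0] - M[:, 0, 1] * ga[:, 1]) / dsafe
            s1 = (M[:, 0, 0] * ga[:, 1] - M[:, 0, 1] * ga[:, 0]) / dsafe
            steps = np.column_stack([s0, s1])
            fb = ~good
            if np.any(fb):
                ok = False
                steps[fb] = np.clip(ga[fb], -1.0, 1.0)
        # damped update: halve steps for subjects that do not improve
        scale = np.ones(n)
        for _h in range(10):
            u_try = u.copy()
            u_try[:, idx] = u[:, idx] + scale[:, None] * steps
            obj_try = objective(u_try)
            worse = obj_try < obj - 1e-12
            if not np.any(worse):
                u, obj = u_try, obj_try
                break
            scale[worse] *= 0.5
        else:
            improved = obj_try >= obj
            u[improved] = u_try[improved]
            obj = np.maximum(obj, obj_try)
    else:
        ok = False
    return u, ok


def _component_marginal(comp: _Component, pv: ParameterVector, G: np.ndarray,
                        quad: QuadratureConfig, modes_cache=None):
    """Per-subject log marginal likelihood of one component.

    Returns (loglik (n,), modes (n, d), mode_search_ok).
    """
    n, d = comp.n, comp.dim
    sds = np.sqrt(np.diag(G))
    act = sds > _SD_TOL
    d_act = int(act.sum())
    if d_act == 0:
        ll = comp.cond_loglik(pv, np.zeros((n, 1, d)))[:, 0]
        return ll, np.zeros((n, d)), True
    idx = np.flatnonzero(act)
    G_act = G[np.ix_(idx, idx)]
    Ginv = np.linalg.inv(G_act)
    sign, logdetG = np.linalg.slogdet(G_act)

    ok = True
    if quad.adaptive:
        u0 = modes_cache if modes_cache is not None else None
        modes, ok = _search_modes(comp, pv, act, Ginv, quad, u0=u0)
        _, H = comp.cond_grad_hess(pv, modes)
        Hpd = Ginv[None, :, :] - H[np.ix_(np.arange(n), idx, idx)]
    else:
        modes = np.zeros((n, d))
        Hpd = np.broadcast_to(Ginv, (n, d_act, d_act)).copy()

    T, logw, tsq = _hermite_nodes(quad.nodes_per_dim, d_act)
    Q = len(logw)

    if d_act == 1:
        h = Hpd[:, 0, 0]
        bad = h <= 0
        if np.any(bad):
            h = np.where(bad, Ginv[0, 0], h)
        A = 1.0 / np.sqrt(h)
        logdetA = np.log(A)
        U_act = modes[:, idx[0]][:, None] + np.sqrt(2.0) * A[:, None] * T[:, 0][None, :]
        U_act = U_act[:, :, None]
    else:
        h11, h12, h22 = Hpd[:, 0, 0], Hpd[:, 0, 1], Hpd[:, 1, 1]
        det = h11 * h22 - h12**2
        bad = (h11 <= 0) | (det <= 0)
        if np.any(bad):
            h11 = np.where(bad, Ginv[0, 0], h11)
            h12 = np.where(bad, Ginv[0, 1], h12)
            h22 = np.where(bad, Ginv[1, 1], h22)
        c11 = np.sqrt(h11)
        c21 = h12 / c11
        c22 = np.sqrt(np.maximum(h22 - c21**2, 1e-300))
        logdetA = -(np.log(c11) + np.log(c22))
        # A = C^{-T} (upper triangular), rows of A scale the Hermite nodes
        a11 = 1.0 / c11
        a12 = -c21 / (c11 * c22)
        a22 = 1.0 / c22
        U_act = np.empty((n, Q, 2))
        U_act[:, :, 0] = modes[:, idx[0], None] + np.sqrt(2.0) * (
            a11[:, None] * T[None, :, 0] + a12[:, None] * T[None, :, 1]
        )
        U_act[:, :, 1] = modes[:, idx[1], None] + np.sqrt(2.0) * (
            a22[:, None] * T[None, :, 1]
        )

    U = np.zeros((n, Q, d))
    for j, dim_j in enumerate(idx):
        U[:, :, dim_j] = U_act[:, :, j]

    ll_nodes = comp.cond_loglik(pv, U)
    quad_form = np.einsum("nqi,ij,nqj->nq", U_act, Ginv, U_act)
    log_prior = -0.5 * d_act * np.log(2.0 * np.pi) - 0.5 * logdetG - 0.5 * quad_form
    logmarg = (
        0.5 * d_act * np.log(2.0)
        + logdetA
        + logsumexp(logw[None, :] + tsq[None, :] + ll_nodes + log_prior, axis=1)
    )
    return logmarg, modes, ok


# ---------------------------------------------------------------------------
# public likelihood surface
# ---------------------------------------------------------------------------


def _components_for(dataset: PanelDataset, spec: ModelSpec, zero_constant=None):
    """Build the likelihood components of a family."""
    fam = spec.family
    if fam in ("mtp", "tp_correlated"):
        return [_Component("joint", dataset, spec)]
    if fam == "tp_uncorrelated":
        return [
            _Component("binary", dataset, spec),
            _Component("cont", dataset, spec, positives_only=True),
        ]
    # one_part: replace zeros by a small constant, model all records
    y = dataset.y.copy()
    zeros = y <= spec.zero_threshold
    if np.any(zeros):
        if zero_constant is None:
            pos = y[~zeros]
            if len(pos) == 0:
                raise ValueError("one-part model needs at least one positive outcome")
            zero_constant = 0.5 * float(np.min(pos))
        y[zeros] = zero_constant
    comp = _Component("cont", dataset, spec, use_w=True, y_override=y)
    comp.zero_constant = zero_constant
    return [comp]


def _component_G(comp: _Component, pv: ParameterVector):
    re = pv.re_cov
    if comp.kind == "joint":
        return re.matrix()
    if comp.kind == "binary":
        return np.array([[re.var1]])
    return np.array([[re.var2]])


def marginal_subject_loglik(y, Z, X, params: ParameterVector, spec: ModelSpec,
                            quad: QuadratureConfig | None = None, W=None):
    """Log marginal likelihood of a single subject's records.

    The random effects are integrated out by (adaptive) Gauss-Hermite
    quadrature: a 2-D tensor rule for ``tp_correlated`` / ``mtp``, 1-D per
    part for ``tp_uncorrelated``, 1-D for ``one_part`` (whose zeros must
    already have been replaced by a positive constant).  With all
    random-effect variances zero this reduces exactly to the log integrand
    at u = 0.
    """
    quad = quad or QuadratureConfig()
    y = np.atleast_1d(np.asarray(y, dtype=float))
    m = len(y)
    ds = PanelDataset(
        subject=np.zeros(m, dtype=int),
        time=np.arange(m, dtype=float),
        y=y,
        Z=np.atleast_2d(Z),
        X=np.atleast_2d(X),
        W=None if W is None else np.atleast_2d(W),
    )
    total = 0.0
    for comp in _components_for(ds, spec):
        ll, _, _ = _component_marginal(comp, params, _component_G(comp, params), quad)
        total += float(ll[0])
    return total


def total_negloglik(theta, dataset: PanelDataset, spec: ModelSpec,
                    quad: QuadratureConfig | None = None):
    """Negative total log marginal likelihood at free parameters ``theta``.

    For ``tp_uncorrelated``, theta is the concatenation of the binary-part
    and continuous-part free vectors.
    """
    quad = quad or QuadratureConfig()
    p_z, p_x = dataset.Z.shape[1], dataset.X.shape[1]
    if spec.family == "tp_uncorrelated":
        tb = _Transform("binary", spec.distribution, p_z, 0)
        tc = _Transform("cont", spec.distribution, 0, p_x)
        theta = np.asarray(theta, dtype=float)
        pv_b = tb.unpack(theta[: tb.n_free])
        pv_c = tc.unpack(theta[tb.n_free :])
        comps = _components_for(dataset, spec)
        ll_b, _, _ = _component_marginal(comps[0], pv_b, _component_G(comps[0], pv_b), quad)
        ll_c, _, _ = _component_marginal(comps[1], pv_c, _component_G(comps[1], pv_c), quad)
        return -(float(np.sum(ll_b)) + float(np.sum(ll_c)))
    p_coef = dataset.W.shape[1] if spec.family == "one_part" else p_x
    tr = _transform_for(spec, p_z, p_coef)
    pv = tr.unpack(theta)
    comp = _components_for(dataset, spec)[0]
    ll, _, _ = _component_marginal(comp, pv, _component_G(comp, pv), quad)
    return -float(np.sum(ll))


# ---------------------------------------------------------------------------
# finite differences / standard errors
# ---------------------------------------------------------------------------


def fd_hessian(f, x, rel_step: float = 1e-4):
    """Central finite-difference Hessian; step scaled per parameter."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _fd_jacobian(f, x, rel_step: float = 1e-6):
    x = np.asarray(x, dtype=float)
    h = rel_step * np.maximum(1.0, np.abs(x))
    cols = []
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h[i]
        cols.append((np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2.0 * h[i]))
    return np.column_stack(cols)


def compute_standard_errors(hessian: np.ndarray, transform_jacobian: np.ndarray | None = None):
    """SEs and covariance from the observed information.

    ``hessian`` is the Hessian of the *negative* log-likelihood at the
    optimum on the unconstrained scale; ``transform_jacobian`` maps
    unconstrained to natural parameters (delta method).  Returns
    ``(se, vcov, ok)``; a singular/indefinite Hessian yields NaN SEs for the
    affected parameters and ``ok = False`` (boundary-solution warning).
    """
    hessian = np.asarray(hessian, dtype=float)
    ok = True
    try:
        eigs = np.linalg.eigvalsh(hessian)
        if np.min(eigs) <= 0:
            ok = False
        vcov = np.linalg.inv(hessian) if ok else np.linalg.pinv(hessian)
    except np.linalg.LinAlgError:
        ok = False
        vcov = np.linalg.pinv(hessian)
    if transform_jacobian is not None:
        J = np.asarray(transform_jacobian, dtype=float)
        vcov = J @ vcov @ J.T
    diag = np.diag(vcov).copy()
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.where(diag >= 0, diag, np.nan))
    if np.any(~np.isfinite(se)):
        ok = False
    return se, vcov, ok


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------


def _start_binary(dataset: PanelDataset, spec: ModelSpec):
    import statsmodels.api as sm

    nz = classify_zero(dataset.y, spec)
    try:
        res = sm.GLM(nz, dataset.Z, family=sm.families.Binomial()).fit()
        alpha = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(alpha)) or np.max(np.abs(alpha)) > 20:
            raise ValueError
    except Exception:
        alpha = np.zeros(dataset.Z.shape[1])
        pbar = np.clip(np.mean(nz), 1e-3, 1 - 1e-3)
        alpha[0] = np.log(pbar / (1 - pbar))
    return alpha


def _start_continuous(y_pos, X_pos, distribution: str):
    import statsmodels.api as sm

    try:
        res = sm.GLM(y_pos, X_pos, family=sm.families.Gamma(sm.families.links.Log())).fit()
        coef = np.asarray(res.params, dtype=float)
        fitted = np.asarray(res.fittedvalues, dtype=float)
        if not np.all(np.isfinite(coef)):
            raise ValueError
    except Exception:
        coef, _, _, _ = np.linalg.lstsq(X_pos, np.log(y_pos), rcond=None)
        fitted = np.exp(X_pos @ coef)
    cv = float(np.std(y_pos / np.maximum(fitted, 1e-12)))
    k0 = float(np.clip(cv, 0.15, 2.5))
    sd_log = float(np.clip(np.std(np.log(y_pos) - np.log(np.maximum(fitted, 1e-12))), 0.15, 2.5))
    if distribution == "gamma":
        k, sigma = k0, k0
    elif distribution == "weibull":
        k, sigma = 1.0, sd_log
    elif distribution == "lognormal":
        k, sigma = 0.0, sd_log
    else:  # gg
        k, sigma = k0, k0
    return coef, k, sigma


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _minimize_component(comps, transforms, theta0, dataset, spec, quad, opts):
    """BFGS on the (joint) free vector of one or more tied components."""
    modes_cache = [None] * len(comps)

    splits = np.cumsum([t.n_free for t in transforms])[:-1]

    def negll(theta):
        total = 0.0
        for ci, (comp, tr, th) in enumerate(zip(comps, transforms, np.split(theta, splits))):
            pv = tr.unpack(th)
            G = _component_G(comp, pv)
            ll, modes, _ = _component_marginal(comp, pv, G, quad, modes_cache=modes_cache[ci])
            modes_cache[ci] = modes
            total -= float(np.sum(ll))
        if not np.isfinite(total):
            total = 1e12
        return total

    res = minimize(negll, theta0, method="BFGS",
                   options={"gtol": opts.gtol, "maxiter": opts.maxiter})
    gnorm = float(np.max(np.abs(res.jac)))
    # the FD-gradient noise floor scales with |f|; accept a gradient at that
    # floor as converged (the BFGS line search has stalled there by then)
    converged = bool(res.success or gnorm < max(opts.gtol, 2e-6 * max(1.0, abs(res.fun))))
    return res, negll, converged, gnorm


def _eb_modes(comps, pvs, quad):
    """Posterior modes per subject, assembled into an (n, 2) array."""
    n = comps[0].n
    eb = np.zeros((n, 2))
    flags = True
    for comp, pv in zip(comps, pvs):
        G = _component_G(comp, pv)
        sds = np.sqrt(np.diag(G))
        act = sds > _SD_TOL
        if not np.any(act):
            continue
        idx = np.flatnonzero(act)
        Ginv = np.linalg.inv(G[np.ix_(idx, idx)])
        modes, _ = _search_modes(comp, pv, act, Ginv, quad)
        # judge by the final stationarity, not by transient fallback steps
        g, _h = comp.cond_grad_hess(pv, modes)
        ga = g[:, idx] - modes[:, idx] @ Ginv
        flags &= bool(np.max(np.abs(ga)) < 1e-4)
        if comp.kind == "joint":
            eb[:, :] = modes
        elif comp.kind == "binary":
            eb[:, 0] = modes[:, 0]
        else:
            eb[:, 1] = modes[:, 0]
    return eb, flags


def fit_model(dataset: PanelDataset, spec: ModelSpec,
              quad: QuadratureConfig | None = None,
              options: FitOptions | None = None,
              warm_start: ParameterVector | None = None) -> FitResult:
    """Fit one family by maximum marginal likelihood.

    Quasi-Newton (BFGS) on the unconstrained scale; ``tp_uncorrelated`` fits
    its binary and continuous parts as two independent one-random-effect
    problems and reports them jointly.  Non-convergence is reported in the
    result, never silently.
    """
    quad = quad or QuadratureConfig()
    opts = options or FitOptions()
    t0 = _time.time()
    nz = classify_zero(dataset.y, spec)
    if spec.family != "one_part":
        if nz.sum() == 0 or nz.sum() == len(nz):
            raise ValueError("two-part families need both zero and positive outcomes")

    p_z, p_x, p_w = dataset.Z.shape[1], dataset.X.shape[1], dataset.W.shape[1]
    messages: list[str] = []

    comps = _components_for(dataset, spec, zero_constant=opts.zero_constant)
    y_pos = dataset.y[nz.astype(bool)]

    if spec.family == "tp_uncorrelated":
        transforms = [
            _Transform("binary", spec.distribution, p_z, 0),
            _Transform("cont", spec.distribution, 0, p_x),
        ]
        if warm_start is not None:
            theta0 = np.concatenate([
                transforms[0].pack(warm_start), transforms[1].pack(warm_start)
            ])
        else:
            alpha0 = _start_binary(dataset, spec)
            coef0, k0, s0 = _start_continuous(y_pos, dataset.X[nz.astype(bool)], spec.distribution)
            pv_b = ParameterVector(np.zeros(0), k0, s0, RandomEffectsCov(0.25, 0, 0, False), alpha0)
            pv_c = ParameterVector(coef0, k0, s0, RandomEffectsCov(0, 0.25, 0, False), None)
            theta0 = np.concatenate([transforms[0].pack(pv_b), transforms[1].pack(pv_c)])
    elif spec.family == "one_part":
        transforms = [_Transform("one_part", spec.distribution, 0, p_w)]
        if warm_start is not None:
            theta0 = transforms[0].pack(warm_start)
        else:
            y_adj = comps[0].y
            coef0, k0, s0 = _start_continuous(y_adj, comps[0].X, spec.distribution)
            pv0 = ParameterVector(coef0, k0, s0, RandomEffectsCov(0, 0.25, 0, False), None)
            theta0 = transforms[0].pack(pv0)
        messages.append(f"one-part zero replacement constant c = {comps[0].zero_constant:.6g}")
    else:
        transforms = [_Transform("joint", spec.distribution, p_z, p_x)]
        if warm_start is not None:
            theta0 = transforms[0].pack(warm_start)
        else:
            alpha0 = _start_binary(dataset, spec)
            coef0, k0, s0 = _start_continuous(y_pos, dataset.X[nz.astype(bool)], spec.distribution)
            pv0 = ParameterVector(coef0, k0, s0,
                                  RandomEffectsCov(0.25, 0.25, 0.0, True), alpha0)
            if spec.family == "mtp" and opts.pre_fit:
                try:
                    pre = fit_model(dataset, replace(spec, family="tp_correlated"), quad,
                                    FitOptions(maxiter=200, gtol=1e-3, pre_fit=False))
                    pv0 = pre.estimates
                    messages.append("warm-started from tp_correlated solution")
                except Exception as exc:  # pragma: no cover
                    messages.append(f"tp_correlated pre-fit failed ({exc}); stage-wise start")
            theta0 = transforms[0].pack(pv0)

    res, negll, converged, gnorm = _minimize_component(
        comps, transforms, theta0, dataset, spec, quad, opts
    )
    theta_hat = np.asarray(res.x, dtype=float)
    loglik = -float(res.fun)

    # assemble the combined parameter vector
    splits = np.cumsum([t.n_free for t in transforms])[:-1]
    pvs = [t.unpack(th) for t, th in zip(transforms, np.split(theta_hat, splits))]
    if spec.family == "tp_uncorrelated":
        pv_b, pv_c = pvs
        estimates = ParameterVector(
            cont_coef=pv_c.cont_coef, k=pv_c.k, sigma=pv_c.sigma,
            re_cov=RandomEffectsCov(pv_b.re_cov.var1, pv_c.re_cov.var2, 0.0, correlated=False),
            alpha=pv_b.alpha,
        )
    else:
        estimates = pvs[0]

    n_params = sum(t.n_free for t in transforms)
    n_subjects = dataset.n_subjects
    aic, bic, _ = information_criteria(loglik, n_params, n_subjects)

    def nat(theta):
        return np.concatenate([
            t.natural(th) for t, th in zip(transforms, np.split(theta, splits))
        ])

    # observed information -> natural-scale SEs (delta method)
    if opts.compute_se:
        hess = fd_hessian(negll, theta_hat)
        J = _fd_jacobian(nat, theta_hat)
        se, vcov, se_ok = compute_standard_errors(hess, J)
        if not se_ok:
            messages.append(
                "observed information not positive definite: boundary solution "
                "suspected; some SEs undefined"
            )
    else:
        se = np.full(len(nat(theta_hat)), np.nan)
        vcov = np.full((len(se), len(se)), np.nan)
        messages.append("standard errors not requested")

    roles = spec.roles or {}
    z_names = roles.get("z")
    x_role = "w" if spec.family == "one_part" else "x"
    x_names = roles.get(x_role)
    name_parts = []
    for t in transforms:
        a_names = ([f"alpha:{c}" for c in z_names]
                   if t.p_alpha and z_names and len(z_names) == t.p_alpha else None)
        c_names = ([f"cont:{c}" for c in x_names]
                   if t.p_coef and x_names and len(x_names) == t.p_coef else None)
        name_parts += t.natural_names(alpha_names=a_names, coef_names=c_names)
    eb, eb_ok = _eb_modes(comps, pvs, quad)
    if not eb_ok:
        messages.append("posterior-mode search hit its fallback for some subjects")

    return FitResult(
        estimates=estimates,
        spec=spec,
        param_names=name_parts,
        theta=theta_hat,
        natural=nat(theta_hat),
        se=se,
        vcov=vcov,
        loglik=loglik,
        n_params=n_params,
        n_subjects=n_subjects,
        aic=aic,
        bic=bic,
        converged=converged,
        n_iter=int(res.nit),
        gradient_norm=gnorm,
        eb_effects=eb,
        messages=messages,
        extra={
            "runtime_s": _time.time() - t0,
            "optimizer_status": res.status,
            "optimizer_message": res.message,
            "zero_constant": getattr(comps[0], "zero_constant", None),
        },
    )


def predict_random_effects(dataset: PanelDataset, fit: FitResult,
                           quad: QuadratureConfig | None = None) -> np.ndarray:
    """Empirical-Bayes predictions: posterior modes of (u1, u2) at the MLE.

    These are the centering points of the adaptive quadrature; they shrink
    toward 0 as a subject contributes fewer records.
    """
    quad = quad or QuadratureConfig()
    spec = fit.spec
    comps = _components_for(dataset, spec, zero_constant=fit.extra.get("zero_constant"))
    if spec.family == "tp_uncorrelated":
        re = fit.estimates.re_cov
        pv_b = ParameterVector(np.zeros(0), fit.estimates.k, fit.estimates.sigma,
                               RandomEffectsCov(re.var1, 0, 0, False), fit.estimates.alpha)
        pv_c = ParameterVector(fit.estimates.cont_coef, fit.estimates.k, fit.estimates.sigma,
                               RandomEffectsCov(0, re.var2, 0, False), None)
        pvs = [pv_b, pv_c]
    else:
        pvs = [fit.estimates]
    eb, _ = _eb_modes(comps, pvs, quad)
    return eb
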
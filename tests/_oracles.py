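"""Shared independent oracles for the test suite."""

import numpy as np


def brute_force_subject_loglik(y, Z, X, params, spec, grid=161, width=8.0):
    """Independent 2-D trapezoid integration of the subject likelihood.

    Deliberately slow and simple: loops over a dense (u1, u2) grid, calling
    the scalar per-subject integrand, and integrates against the bivariate
    normal prior by the trapezoid rule.
    """
    from scipy.stats import multivariate_normal

    from mtplong.model import subject_log_integrand

    G = params.re_cov.matrix()
    s1, s2 = np.sqrt(G[0, 0]), np.sqrt(G[1, 1])
    u1 = np.linspace(-width * s1, width * s1, grid)
    u2 = np.linspace(-width * s2, width * s2, grid)
    vals = np.empty((grid, grid))
    for i, a in enumerate(u1):
        for j, b in enumerate(u2):
            vals[i, j] = subject_log_integrand(y, Z, X, params, spec, (a, b))
    U1, U2 = np.meshgrid(u1, u2, indexing="ij")
    pdf = multivariate_normal(mean=[0, 0], cov=G).pdf(np.dstack([U1, U2]))
    integral = np.trapezoid(np.trapezoid(np.exp(vals) * pdf, u2, axis=1), u1)
    return float(np.log(integral))
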
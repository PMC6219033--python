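"""The generalized gamma family: density, mean offset, special cases.

The continuous (positive) part of every model in this package comes from the
three-parameter generalized gamma family, which nests the gamma
(sigma == k), Weibull (k == 1) and lognormal (k -> 0) distributions.  The
log-scale offset C(sigma, k) links the location parameter to the mean:
E(Y) = exp(mu + C).
"""

import numpy as np

from mtplong import GGParams, gg_mean, gg_sample, gg_variance, offset_C

for label, p in [
    ("gamma (sigma=k=0.5)", GGParams(k=0.5, sigma=0.5, mu=0.2)),
    ("Weibull (k=1)", GGParams(k=1.0, sigma=0.7, mu=0.2)),
    ("lognormal (k=0)", GGParams(k=0.0, sigma=0.7, mu=0.2)),
    ("full GG", GGParams(k=0.6, sigma=0.9, mu=0.2)),
]:
    s = gg_sample(p, 100_000, np.random.default_rng(1))
    print(f"{label:22s} C={offset_C(p.sigma, p.k):+.4f}  "
          f"mean={gg_mean(p):.4f} (sample {s.mean():.4f})  "
          f"var={gg_variance(p):.4f} (sample {s.var():.4f})")

# The printed C is the amount by which log E(Y) exceeds the location mu;
# the gamma case has C = 0, so there mu IS the log mean.  Sample moments of
# 1e5 draws agree with the closed forms to Monte-Carlo accuracy.
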
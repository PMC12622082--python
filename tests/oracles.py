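"""Independent brute-force references used to check the vectorized model code.

Everything here is deliberately naive: plain Python loops over all 3^K
configurations with scipy densities, with no code shared with the package's
log-space vectorized implementation.
"""

import itertools

import numpy as np
from scipy.stats import norm


def naive_config_density(z, h, lam, mu, tau2):
    """Product over cohorts of null/alternative mixture densities."""
    dens = 1.0
    for k, hk in enumerate(h):
        if hk == 0:
            dens *= norm.pdf(z[k])
        else:
            dens *= sum(
                l * norm.pdf(z[k], hk * m, np.sqrt(t))
                for l, m, t in zip(lam[k], mu[k], tau2[k])
            )
    return dens


def naive_lfdr(z, pattern_weights, lam, mu, tau2):
    """Per-variant posterior null mass by direct summation over configurations."""
    K = len(z)
    num = den = 0.0
    for h in itertools.product((-1, 0, 1), repeat=K):
        nnz = sum(1 for x in h if x != 0)
        code = sum(1 << (K - 1 - i) for i, x in enumerate(h) if x != 0)
        prior = pattern_weights[code] / 2.0**nnz
        term = prior * naive_config_density(z, h, lam, mu, tau2)
        den += term
        if not (all(x == 1 for x in h) or all(x == -1 for x in h)):
            num += term
    return num / den


def naive_lfdr_from_fit(Z, fit):
    Z = np.atleast_2d(Z)
    return np.array(
        [naive_lfdr(z, fit.pattern_weights, fit.lam, fit.mu, fit.tau2) for z in Z]
    )
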
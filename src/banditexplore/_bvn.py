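"""Vectorised standard bivariate normal CDF via Owen's T function.

Used for the probability-of-maximum-utility (Thompson) choice rule, where
each bandit's choice probability is a positive-orthant probability of a
bivariate normal of pairwise value differences.  Owen's (1956) identity

    Phi2(h, k, rho) = (Phi(h) + Phi(k)) / 2
                      - T(h, (k - rho h) / (h sqrt(1 - rho^2)))
                      - T(k, (h - rho k) / (k sqrt(1 - rho^2)))
                      - beta

with beta = 1/2 when h k < 0 (or h k = 0 and h + k < 0), gives the CDF to
near machine precision and vectorises through ``scipy.special.owens_t``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "orthant_upper"]

_EPS = 1e-13


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Broadcasts over array inputs; |rho| = 1 handled by the degenerate limits.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, float)

    near_one = np.abs(rho) > 1.0 - 1e-12
    if np.any(near_one):
        pos = near_one & (rho > 0)
        neg = near_one & (rho < 0)
        out[pos] = ndtr(np.minimum(h[pos], k[pos]))
        out[neg] = np.maximum(ndtr(h[neg]) + ndtr(k[neg]) - 1.0, 0.0)

    reg = ~near_one
    if np.any(reg):
        hh = h[reg].copy()
        kk = k[reg].copy()
        r = rho[reg]
        # nudge exact zeros off the removable singularity of Owen's identity
        hh[hh == 0.0] = _EPS
        kk[kk == 0.0] = _EPS
        root = np.sqrt(1.0 - r * r)
        ah = (kk - r * hh) / (hh * root)
        ak = (hh - r * kk) / (kk * root)
        beta = np.where(hh * kk < 0.0, 0.5, 0.0)
        val = 0.5 * (ndtr(hh) + ndtr(kk)) - owens_t(hh, ah) - owens_t(kk, ak) - beta
        out[reg] = val

    return np.clip(out, 0.0, 1.0)


def orthant_upper(mean1, mean2, var1, var2, cov):
    """P(U1 > 0, U2 > 0) for a bivariate normal (vectorised).

    Equals Phi2(m1/s1, m2/s2, rho) with rho = cov / (s1 s2).
    """
    s1 = np.sqrt(var1)
    s2 = np.sqrt(var2)
    rho = cov / (s1 * s2)
    return bvn_cdf(mean1 / s1, mean2 / s2, rho)
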
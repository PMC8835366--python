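"""Vectorized standard bivariate normal CDF via Gauss–Legendre quadrature.

Uses the single-integral identity

    Phi2(h, k, rho) = Phi(h) Phi(k)
        + 1/(2 pi) * int_0^rho (1-r^2)^(-1/2)
              exp(-(h^2 + k^2 - 2 h k r) / (2 (1-r^2))) dr

with the substitution r = sin(t), which removes the endpoint singularity
and leaves a smooth integrand on [0, arcsin(rho)].  A 96-point rule gives
absolute accuracy well below 1e-12 over rho in (-0.9999, 0.9999), and the
routine is vectorized over ``rho`` — the property that makes dense
grid searches over the correlation cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy.special import roots_legendre

_NODES, _WEIGHTS = roots_legendre(96)


def bvn_cdf(h: float, k: float, rho) -> np.ndarray | float:
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized in rho."""
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(np.abs(rho_arr) >= 1.0):
        raise ValueError("rho must lie strictly inside (-1, 1)")
    upper = np.arcsin(rho_arr)  # (m,)
    # t nodes: map [-1,1] -> [0, upper]; shape (m, q)
    t = 0.5 * upper[:, None] * (_NODES[None, :] + 1.0)
    w = 0.5 * upper[:, None] * _WEIGHTS[None, :]
    sin_t = np.sin(t)
    cos2_t = np.cos(t) ** 2
    integrand = np.exp(-(h * h + k * k - 2.0 * h * k * sin_t) / (2.0 * cos2_t))
    integral = np.sum(w * integrand, axis=1) / (2.0 * np.pi)
    out = ndtr(h) * ndtr(k) + integral
    if np.isscalar(rho) or np.asarray(rho).ndim == 0:
        return float(out[0])
    return out


def bvn_quadrant(h: float, k: float, rho) -> np.ndarray | float:
    """Upper-quadrant probability P(X > h, Y > k), vectorized in rho."""
    return bvn_cdf(h, k, rho) - ndtr(h) - ndtr(k) + 1.0
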
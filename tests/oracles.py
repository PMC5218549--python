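"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: the
probit oracle maximizes the likelihood by exhaustive grid search, the
circumcircle oracle checks the Delaunay property over all point triples,
and the effects oracle differentiates the reduced-form choice
probability numerically.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def probit_loglik(b0: np.ndarray, b1: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Vectorized probit log-likelihood over a (b0, b1) grid."""
    eta = b0[..., None] + b1[..., None] * x  # (..., n)
    return np.where(y == 1, norm.logcdf(eta), norm.logcdf(-eta)).sum(axis=-1)


def grid_search_probit(x: np.ndarray, y: np.ndarray, lo=-5.0, hi=5.0,
                       coarse=0.01, fine=0.001) -> tuple[float, float]:
    """Exhaustive 2-D grid maximization of the probit likelihood.

    A coarse pass over [lo, hi]² followed by a fine pass (step ``fine``)
    in a window around the coarse optimum.
    """
    g = np.arange(lo, hi + coarse / 2, coarse)
    B0, B1 = np.meshgrid(g, g, indexing="ij")
    ll = probit_loglik(B0, B1, x, y)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    c0, c1 = g[i], g[j]
    g0 = np.arange(c0 - 2 * coarse, c0 + 2 * coarse + fine / 2, fine)
    g1 = np.arange(c1 - 2 * coarse, c1 + 2 * coarse + fine / 2, fine)
    B0, B1 = np.meshgrid(g0, g1, indexing="ij")
    ll = probit_loglik(B0, B1, x, y)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(B0[i, j]), float(B1[i, j])


def circumcircle_contains(tri_pts: np.ndarray, p: np.ndarray) -> bool:
    """True if point p lies strictly inside the circumcircle of a triangle.

    Classic in-circle determinant test, orientation-corrected.
    """
    a, b, c = tri_pts
    mat = np.array(
        [
            [a[0] - p[0], a[1] - p[1], (a[0] - p[0]) ** 2 + (a[1] - p[1]) ** 2],
            [b[0] - p[0], b[1] - p[1], (b[0] - p[0]) ** 2 + (b[1] - p[1]) ** 2],
            [c[0] - p[0], c[1] - p[1], (c[0] - p[0]) ** 2 + (c[1] - p[1]) ** 2],
        ]
    )
    orient = np.linalg.det(
        np.array([[b[0] - a[0], b[1] - a[1]], [c[0] - a[0], c[1] - a[1]]])
    )
    det = np.linalg.det(mat)
    # strictly inside, with a tolerance scaled to coordinate magnitude
    scale = max(1.0, np.abs(tri_pts).max()) ** 3
    return det * np.sign(orient) > 1e-9 * scale


def fd_effects_matrix(beta_r_index: int, beta: np.ndarray, rho: float,
                      W: np.ndarray, X: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Finite-difference ∂P(y_i=1)/∂x_{j,r} through the reduced form.

    Perturbs covariate r at observation j and differentiates
    Φ([(I−ρW)⁻¹Xβ]_i) numerically; independent of the analytic
    impact-matrix construction.
    """
    n = X.shape[0]
    Ainv = np.linalg.inv(np.eye(n) - rho * W)

    def probs(Xp):
        return norm.cdf(Ainv @ (Xp @ beta))

    out = np.empty((n, n))
    for j in range(n):
        Xp, Xm = X.copy(), X.copy()
        Xp[j, beta_r_index] += h
        Xm[j, beta_r_index] -= h
        out[:, j] = (probs(Xp) - probs(Xm)) / (2 * h)
    return out
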
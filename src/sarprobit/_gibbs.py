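"""Compiled inner loops for the latent-variable Gibbs sweep.

The latent utilities y* of the spatial probit have joint distribution
N(μ, H⁻¹) with precision H = (I−ρW)'(I−ρW) and Hμ = (I−ρW)'Xβ.  A
single-site Gibbs sweep updates each y*_i from its univariate normal
conditional truncated to (0,∞) when the observed outcome is 1 and to
(−∞,0] when it is 0.  Truncated normals are drawn by naive rejection in
the bulk and Robert's exponential rejection sampler in the tail.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _tnorm_lower(m: float, sd: float, lo: float) -> float:
    """Draw from N(m, sd²) truncated to (lo, ∞)."""
    a = (lo - m) / sd
    if not np.isfinite(a):
        raise ValueError("non-finite conditional mean in latent sweep")
    if a < 0.45:
        while True:
            z = np.random.normal()
            if z > a:
                return m + sd * z
    else:
        # Robert (1995) translated-exponential proposal for the tail.
        c = (a + math.sqrt(a * a + 4.0)) / 2.0
        while True:
            z = a + np.random.exponential() / c
            if np.random.random() <= math.exp(-0.5 * (z - c) ** 2):
                return m + sd * z


@njit(cache=True)
def latent_sweep(
    indptr: np.ndarray,
    indices: np.ndarray,
    data: np.ndarray,
    diag: np.ndarray,
    b: np.ndarray,
    y: np.ndarray,
    ystar: np.ndarray,
    seed: int,
) -> None:
    """One in-place single-site Gibbs sweep over y* in index order.

    (indptr, indices, data) is the CSR form of the precision H, diag its
    diagonal, and b = Hμ = (I−ρW)'Xβ.  The conditional of site i is
    N((b_i − Σ_{j≠i} H_ij y*_j)/H_ii, 1/H_ii) truncated by the sign
    constraint of outcome y_i.
    """
    np.random.seed(seed)
    for i in range(ystar.shape[0]):
        s = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j != i:
                s += data[p] * ystar[j]
        m = (b[i] - s) / diag[i]
        sd = 1.0 / math.sqrt(diag[i])
        if y[i] == 1:
            ystar[i] = _tnorm_lower(m, sd, 0.0)
        else:
            ystar[i] = -_tnorm_lower(-m, sd, 0.0)
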
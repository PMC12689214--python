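"""Spherical-spline machinery (Perrin et al. parameterization).

Implements the two standard scalp operators built from spherical
splines on unit-sphere electrode positions:

* interpolation of potentials at bad electrodes from the remaining
  good ones, and
* the surface Laplacian / scalp current density (CSD) transform.

Both are linear maps and are returned as matrices so that they can be
applied per trial and per sample with a single ``@``.

The spline order ``m`` (stiffness), the regularization ``lam`` added
to the diagonal of the spline matrix, and the number of Legendre terms
follow the common Perrin parameterization (m=4, lam=1e-5, 50 terms).
"""

from __future__ import annotations

import numpy as np


def _legendre_weighted_sum(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """sum_n weights[n-1] * P_n(x) for n = 1..len(weights), via recurrence."""
    x = np.asarray(x, dtype=float)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()          # P_1
    out = weights[0] * p_cur
    for n in range(1, len(weights)):
        # P_{n+1}(x) = ((2n+1) x P_n - n P_{n-1}) / (n+1)
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        p_prev, p_cur = p_cur, p_next
        out += weights[n] * p_cur
    return out


def spline_g(cosang: np.ndarray, m: int = 4, n_legendre: int = 50) -> np.ndarray:
    """Perrin g-function matrix (potential spline kernel)."""
    n = np.arange(1, n_legendre + 1, dtype=float)
    w = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    return _legendre_weighted_sum(cosang, w)


def spline_h(cosang: np.ndarray, m: int = 4, n_legendre: int = 50) -> np.ndarray:
    """Perrin h-function matrix (surface-Laplacian spline kernel)."""
    n = np.arange(1, n_legendre + 1, dtype=float)
    w = (2 * n + 1) / (n * (n + 1)) ** (m - 1) / (4 * np.pi)
    return _legendre_weighted_sum(cosang, w)


def _check_positions(pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, dtype=float)
    norms = np.linalg.norm(pos, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("electrode positions must lie on the unit sphere")
    cos = np.clip(pos @ pos.T, -1.0, 1.0)
    off = cos - np.eye(len(pos))
    if np.any(off > 1.0 - 1e-10):
        raise ValueError("degenerate montage: coincident electrode positions")
    return pos


def _augmented_solve(g: np.ndarray, lam: float) -> np.ndarray:
    """Inverse of [[G + lam*I, 1], [1^T, 0]] (spline fit with zero-sum constraint)."""
    n = g.shape[0]
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = g + lam * np.eye(n)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    return np.linalg.inv(a)


def interpolation_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    m: int = 4,
    lam: float = 1e-5,
    n_legendre: int = 50,
) -> np.ndarray:
    """Matrix mapping potentials at good electrodes to bad electrodes.

    Returns ``M`` with shape (n_bad, n_good) such that
    ``V_bad = M @ V_good``.
    """
    pos_good = _check_positions(pos_good)
    pos_bad = np.asarray(pos_bad, dtype=float)
    cos_gg = np.clip(pos_good @ pos_good.T, -1.0, 1.0)
    cos_bg = np.clip(pos_bad @ pos_good.T, -1.0, 1.0)
    g_gg = spline_g(cos_gg, m, n_legendre)
    g_bg = spline_g(cos_bg, m, n_legendre)
    a_inv = _augmented_solve(g_gg, lam)
    n = len(pos_good)
    # [c; c0] = A^-1 [V; 0]; V_bad = G_bg c + c0
    ext = np.hstack([g_bg, np.ones((len(pos_bad), 1))])
    return ext @ a_inv[:, :n]


def csd_matrix(
    pos: np.ndarray,
    m: int = 4,
    lam: float = 1e-5,
    n_legendre: int = 50,
    head_radius_m: float = 0.095,
) -> np.ndarray:
    """Surface-Laplacian (CSD) matrix for electrodes at unit-sphere ``pos``.

    Returns ``L`` (n x n) such that ``CSD = L @ V``.  With potentials in
    microvolts the output is in uV/m^2 for the given head radius.  A
    spatially uniform potential maps to zero exactly (the spline
    coefficients vanish under the zero-sum constraint).
    """
    pos = _check_positions(pos)
    cos = np.clip(pos @ pos.T, -1.0, 1.0)
    g = spline_g(cos, m, n_legendre)
    h = spline_h(cos, m, n_legendre)
    a_inv = _augmented_solve(g, lam)
    n = len(pos)
    return h @ a_inv[:n, :n] / head_radius_m**2
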
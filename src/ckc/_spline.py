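"""Spherical-spline kernels for scalp interpolation and the surface Laplacian.

The interpolating spline on the unit sphere (Perrin-style) expands two radial
kernels in Legendre polynomials of the inter-electrode cosine angle x:

    g(x) = (1/4pi) * sum_{n=1}^{N} (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = (1/4pi) * sum_{n=1}^{N} (2n+1) / (n(n+1))^(m-1) * P_n(x)

with stiffness m and N expansion terms.  A potential field sampled at
electrodes v is represented as v_i = c0 + sum_j c_j g(x_ij) subject to
sum_j c_j = 0; the surface Laplacian (current source density, up to the
constant 1/r^2 scale of the head radius) at electrode i is
sum_j c_j h(x_ij).  Regularization adds lambda to the diagonal of G.

Both operations are linear in the data, so they are exposed as fixed matrices
applied to all time samples at once.
"""

from __future__ import annotations

import numpy as np

FOUR_PI = 4.0 * np.pi


def _legendre_series(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """sum_n coeffs[n-1] * P_n(x) via the three-term recurrence, n = 1..N."""
    x = np.asarray(x, dtype=float)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    out = coeffs[0] * p_cur
    for n in range(1, len(coeffs)):
        # recurrence for P_{n+1} given P_n (p_cur) and P_{n-1} (p_prev)
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        out += coeffs[n] * p_next
        p_prev, p_cur = p_cur, p_next
    return out


def spline_kernels(
    cosang: np.ndarray, stiffness_m: int = 3, n_terms: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (g, h) kernels at an array of cosine angles."""
    n = np.arange(1, n_terms + 1, dtype=float)
    denom = (n * (n + 1.0)) ** stiffness_m
    cg = (2.0 * n + 1.0) / denom / FOUR_PI
    ch = (2.0 * n + 1.0) / ((n * (n + 1.0)) ** (stiffness_m - 1)) / FOUR_PI
    cosang = np.clip(cosang, -1.0, 1.0)
    return _legendre_series(cosang, cg), _legendre_series(cosang, ch)


def _cosangles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.clip(a @ b.T, -1.0, 1.0)


def _constrained_solve_matrix(G: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, b) with c = A v and c0 = b @ v for the constrained system.

    Solves [[G + lam I, 1], [1^T, 0]] [c; c0] = [v; 0]; co-located electrodes
    make the kernel singular, which surfaces as LinAlgError.
    """
    m = G.shape[0]
    M = np.empty((m + 1, m + 1))
    M[:m, :m] = G + lam * np.eye(m)
    M[:m, m] = 1.0
    M[m, :m] = 1.0
    M[m, m] = 0.0
    Minv = np.linalg.inv(M)
    return Minv[:m, :m], Minv[m, :m]


def csd_operator(
    positions: np.ndarray,
    lam: float,
    stiffness_m: int = 3,
    n_terms: int = 50,
) -> np.ndarray:
    """Linear operator L with csd = L @ v (channels x channels).

    Rows of L sum to ~0: a spatially constant potential has zero surface
    Laplacian, which the constrained solve enforces exactly up to roundoff.
    """
    G, H = spline_kernels(_cosangles(positions, positions), stiffness_m, n_terms)
    A, _ = _constrained_solve_matrix(G, lam)
    return H @ A


def interpolation_operator(
    donor_positions: np.ndarray,
    target_positions: np.ndarray,
    lam: float,
    stiffness_m: int = 3,
    n_terms: int = 50,
) -> np.ndarray:
    """Matrix P with v_target = P @ v_donor (spherical-spline estimate)."""
    G, _ = spline_kernels(
        _cosangles(donor_positions, donor_positions), stiffness_m, n_terms
    )
    A, b = _constrained_solve_matrix(G, lam)
    G_td, _ = spline_kernels(
        _cosangles(target_positions, donor_positions), stiffness_m, n_terms
    )
    return G_td @ A + np.outer(np.ones(len(target_positions)), b)
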
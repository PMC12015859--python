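"""Spherical-spline scalp interpolation and surface Laplacian (CSD).

Both operations share the same machinery: scalp potentials are modelled as a
spherical spline ``v(x) = c0 + sum_i c_i g(cos(x, x_i))`` where the kernel

    g(x) = (1 / 4*pi) * sum_{n=1..N} (2n + 1) / (n(n+1))**m * P_n(x)

is a Legendre series over electrode cosine distances (flexibility order ``m``,
series truncated at ``N`` terms, ridge term ``lambda`` on the diagonal for
noisy data).  Interpolation evaluates the fitted spline at bad-electrode
sites.  The surface Laplacian follows from term-wise differentiation on the
sphere (``Laplacian P_n = -n(n+1) P_n``), i.e. the companion kernel

    h(x) = (1 / 4*pi) * sum_{n=1..N} (2n + 1) / (n(n+1))**(m-1) * P_n(x)

so the current source density estimate is ``CSD = H c / r**2`` with head
radius ``r`` — the *negative* surface Laplacian of the potential, positive
over sources.  A potential equal to a single spherical harmonic of degree n
maps onto ``n(n+1)/r**2`` times itself, which the test suite verifies.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

__all__ = ["spline_g_coeffs", "spline_h_coeffs", "csd_transform",
           "interpolation_operator"]


def _series(kind_coeffs: np.ndarray, cosang: np.ndarray) -> np.ndarray:
    return legendre.legval(np.clip(cosang, -1.0, 1.0), kind_coeffs) / (4.0 * np.pi)


def spline_g_coeffs(m: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    c = np.zeros(n_terms + 1)
    c[1:] = (2 * n + 1) / (n * (n + 1)) ** m
    return c


def spline_h_coeffs(m: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    c = np.zeros(n_terms + 1)
    c[1:] = (2 * n + 1) / (n * (n + 1)) ** (m - 1)
    return c


def _fit_matrix(cosang: np.ndarray, m: int, lam: float, n_terms: int) -> np.ndarray:
    """Inverse of the constrained spline system; returns the (n+1, n+1) solver.

    Solving ``[[G + lam*I, 1], [1^T, 0]] [c; c0] = [v; 0]`` enforces the
    zero-sum constraint on the spline coefficients.
    """
    n = cosang.shape[0]
    G = _series(spline_g_coeffs(m, n_terms), cosang)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    return np.linalg.inv(A)


def csd_transform(positions: np.ndarray, m: int = 4, lam: float = 1e-5,
                  n_terms: int = 50, head_radius_m: float = 0.085) -> np.ndarray:
    """Linear operator mapping scalp potentials (uV) to CSD (uV/m^2).

    Apply as ``csd = T @ v`` per sample (or ``T @ data`` for channels x time).
    """
    cosang = positions @ positions.T
    Ainv = _fit_matrix(cosang, m, lam, n_terms)
    n = positions.shape[0]
    H = _series(spline_h_coeffs(m, n_terms), cosang)
    return (H @ Ainv[:n, :n]) / head_radius_m**2


def interpolation_operator(positions: np.ndarray, good: np.ndarray,
                           bad: np.ndarray, m: int = 4, lam: float = 1e-5,
                           n_terms: int = 50) -> np.ndarray:
    """Linear operator estimating bad-channel potentials from good ones.

    Returns a ``(len(bad), len(good))`` matrix ``W`` with ``v_bad = W @ v_good``.
    Requires at least 4 good electrodes for a stable fit.
    """
    if len(good) < 4:
        raise ValueError("need at least 4 good channels for interpolation")
    pg = positions[good]
    cos_gg = pg @ pg.T
    Ainv = _fit_matrix(cos_gg, m, lam, n_terms)
    ng = len(good)
    cos_bg = positions[bad] @ pg.T
    Gbg = _series(spline_g_coeffs(m, n_terms), cos_bg)
    # v_bad = Gbg @ c + c0;  [c; c0] = Ainv[:, :ng] @ v_good (rhs tail is zero)
    W = np.hstack([Gbg, np.ones((len(bad), 1))]) @ Ainv[:, :ng]
    return W
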
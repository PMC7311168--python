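"""Regularized spherical splines on the unit sphere (Perrin-style).

Shared machinery for channel interpolation and the surface-Laplacian (CSD)
transform.  ``g`` is the spline kernel for interpolating potentials; ``h``
is the corresponding kernel whose expansion yields the negative surface
Laplacian of the fitted spline, so that a degree-l spherical harmonic maps
to l(l+1) times itself.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg


def _kernel_coeffs(m: int, n_terms: int, laplacian: bool) -> np.ndarray:
    """Legendre-series coefficients: (2l+1) / (4*pi * (l(l+1))^p), l = 1..n_terms."""
    ell = np.arange(1, n_terms + 1, dtype=float)
    p = m - 1 if laplacian else m
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * ell + 1) / (4 * np.pi * (ell * (ell + 1)) ** p)
    return coeffs


def kernel_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50,
                  laplacian: bool = False) -> np.ndarray:
    """Evaluate the spline kernel at an array of cosines of angular distances."""
    coeffs = _kernel_coeffs(m, n_terms, laplacian)
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coeffs)


def cosine_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(a) @ np.asarray(b).T, -1.0, 1.0)


def check_positions(positions: np.ndarray) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    if not np.allclose(np.linalg.norm(positions, axis=1), 1.0, atol=1e-6):
        raise ValueError("positions must be unit-norm")
    cos = cosine_distances(positions, positions)
    np.fill_diagonal(cos, -2.0)
    if np.any(cos > 1.0 - 1e-12):
        raise ValueError("duplicate sensor positions (rank-deficient spline system)")
    return positions


def solve_spline(g: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve the constrained spline system for coefficients.

    The Gram matrix is trace-normalized to mean diagonal 1 before the
    regularization weight ``lam`` is added, making ``lam`` comparable across
    montages.  ``y`` may be (n,) or (n, k) for k right-hand sides.  Returns
    (c, d): kernel coefficients (same normalized scale) and the constant.
    """
    n = g.shape[0]
    scale = np.trace(g) / n
    gs = g / scale + lam * np.eye(n)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gs
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    y = np.atleast_1d(np.asarray(y, dtype=float))
    rhs = np.zeros((n + 1,) + y.shape[1:])
    rhs[:n] = y
    sol = np.linalg.solve(a, rhs)
    return sol[:n], sol[n]
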
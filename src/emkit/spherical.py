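"""Deterministic near-equidistant point sets on the unit sphere.

Source grids, synthetic sensor layouts, and interpolation test grids all
need approximately uniform samplings of the sphere.  There is no exact
construction for general n, so we use a generalized spiral (Fibonacci
lattice) followed by a fixed schedule of electrostatic repulsion steps.
The procedure is fully deterministic: same n, same points, on every
platform.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["equidistant_sphere_points", "spherical_cap_points", "min_pairwise_angle"]


def _fibonacci_lattice(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _repulsion_refine(points: np.ndarray, n_iter: int) -> np.ndarray:
    """Push points apart with inverse-square pairwise forces.

    Steps are projected onto the tangent plane and renormalized to the
    sphere.  The step length starts near the nominal inter-point spacing
    and decays linearly to zero, which freezes the configuration.
    """
    x = points.copy()
    n = len(x)
    step0 = 2.0 / n
    for it in range(n_iter):
        d = x[:, None, :] - x[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", d, d)
        np.fill_diagonal(dist2, np.inf)
        f = np.einsum("ijk,ij->ik", d, dist2**-1.5)
        f -= np.sum(f * x, axis=1, keepdims=True) * x
        mag = np.linalg.norm(f, axis=1).max()
        if mag == 0.0:
            break
        x = x + (step0 * (1.0 - it / n_iter) / mag) * f
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


@lru_cache(maxsize=32)
def _cached_points(n: int) -> np.ndarray:
    if n == 2:
        pts = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    else:
        n_iter = 300 if n <= 256 else 200
        pts = _repulsion_refine(_fibonacci_lattice(n), n_iter)
    pts.setflags(write=False)
    return pts


def equidistant_sphere_points(n: int) -> np.ndarray:
    """Return ``n`` approximately equidistant unit vectors.

    Deterministic; ``n = 2`` returns the exact antipodal pair and
    ``n = 4`` converges to the regular tetrahedron.

    Parameters
    ----------
    n
        Number of points, at least 2.
    """
    if n < 2:
        raise ValueError("need at least 2 points on the sphere")
    return _cached_points(int(n)).copy()


def spherical_cap_points(n: int, z_min: float) -> np.ndarray:
    """``n`` spiral points on the cap ``z >= z_min`` of the unit sphere.

    Used for sensor layouts that cover only the upper part of the head.
    Pure spiral construction (no repulsion) so the cap boundary is
    respected exactly; deterministic.
    """
    if n < 1:
        raise ValueError("need at least 1 point")
    i = np.arange(n)
    z = 1.0 - (1.0 - z_min) * (2.0 * i + 1.0) / (2.0 * n)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def min_pairwise_angle(points: np.ndarray) -> float:
    """Smallest pairwise angular distance of a set of unit vectors, in radians."""
    g = np.clip(points @ points.T, -1.0, 1.0)
    np.fill_diagonal(g, -1.0)
    return float(np.arccos(g.max()))
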
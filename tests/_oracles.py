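"""Independent reference implementations used only to check emkit.

These deliberately avoid the package's own code paths: the
homogeneous-sphere potential is the textbook Legendre series with the
closed-form (2n+1)/n boundary factor; the magnetometer oracle is a
Geselowitz surface-integral quadrature over the conductor boundary.
"""

import numpy as np

MU0_OVER_4PI = 1e-7


def legendre_pair(t: np.ndarray, n_max: int):
    """P_n(t) and P'_n(t) for n = 0..n_max via upward recurrences."""
    P = [np.ones_like(t), t.copy()]
    dP = [np.zeros_like(t), np.ones_like(t)]
    for n in range(2, n_max + 1):
        P.append(((2 * n - 1) * t * P[-1] - (n - 1) * P[-2]) / n)
        dP.append(dP[-2] + (2 * n - 1) * P[n - 1])
    return P, dP


def homogeneous_sphere_potential(
    sensor_dirs: np.ndarray,
    radius_m: float,
    src_pos_m: np.ndarray,
    src_moment_Am: np.ndarray,
    sigma: float,
    n_max: int = 400,
) -> np.ndarray:
    """Surface potential (V) of a dipole in a homogeneous conducting sphere.

    Classic series: each degree of the infinite-medium expansion is
    scaled by (2n+1)/n to satisfy the zero-current boundary condition.
    """
    b = float(np.linalg.norm(src_pos_m))
    bdir = src_pos_m / b if b > 0 else np.array([0.0, 0.0, 1.0])
    t = sensor_dirs @ bdir
    qr = float(src_moment_Am @ bdir)
    qtan = sensor_dirs @ src_moment_Am - t * qr
    P, dP = legendre_pair(t, n_max)
    V = np.zeros(len(sensor_dirs))
    for n in range(1, n_max + 1):
        V += (
            (2 * n + 1)
            / n
            * (b / radius_m) ** (n - 1)
            / radius_m**2
            * (n * P[n] * qr + dP[n] * qtan)
            / (4 * np.pi * sigma)
        )
    return V


def fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    phi = i * np.pi * (3 - np.sqrt(5))
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def geselowitz_magnetometer(
    sens_pos_m: np.ndarray,
    sens_ori: np.ndarray,
    src_pos_m: np.ndarray,
    src_moment_Am: np.ndarray,
    conductor_radius_m: float,
    sigma: float,
    n_quad: int = 20000,
) -> np.ndarray:
    """Magnetometer field (T) by numeric integration of the volume
    currents: primary dipole field plus the Geselowitz surface integral
    of the boundary potential over the spherical conductor surface."""
    dirs = fibonacci_sphere(n_quad)
    v_surf = homogeneous_sphere_potential(
        dirs, conductor_radius_m, src_pos_m, src_moment_Am, sigma
    )
    rs = dirs * conductor_radius_m
    dS = 4 * np.pi * conductor_radius_m**2 / n_quad
    out = np.zeros(len(sens_pos_m))
    for i, (r, nrm) in enumerate(zip(sens_pos_m, sens_ori)):
        d = r - rs
        d3 = np.linalg.norm(d, axis=1) ** 3
        b_primary = (
            MU0_OVER_4PI
            * np.cross(src_moment_Am, r - src_pos_m)
            / np.linalg.norm(r - src_pos_m) ** 3
        )
        integrand = np.cross(dirs, d) / d3[:, None]
        b_secondary = -MU0_OVER_4PI * sigma * dS * (v_surf[:, None] * integrand).sum(
            axis=0
        )
        out[i] = (b_primary + b_secondary) @ nrm
    return out
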
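"""Spherical forward models for EEG and MEG.

EEG uses the analytic dipole potential in four concentric conducting
shells (brain, CSF, skull, scalp), expanded per Legendre degree; the
radial boundary-value problem is solved exactly for each degree, so
arbitrary conductivity profiles are supported and the equal-conductivity
case reduces to the classical homogeneous-sphere series.  MEG uses the
closed-form field of a current dipole in a spherically symmetric
conductor (Sarvas), projected onto each magnetometer's coil normal;
radial sources are silent by construction.

Source space: four concentric source shells (default radii 2, 4, 6,
8 cm) each carrying the same number of near-equidistant dipole
locations (default 655), with a local orthonormal orientation frame
(azimuthal, polar, radial) per location.  EEG keeps all three
orientations; MEG drops the silent radial one.

Units: positions in cm, lead fields in µV per nA·m (EEG) and fT per
nA·m (MEG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .containers import SensorLayout
from .spherical import equidistant_sphere_points

__all__ = [
    "HeadModel",
    "SourceModel",
    "LeadField",
    "ConvergenceError",
    "build_source_model",
    "eeg_leadfield",
    "meg_leadfield",
    "forward_dipoles",
]

#: Default conductivities in S/m for brain, CSF, skull, scalp.
DEFAULT_CONDUCTIVITIES = (0.33, 1.0, 0.0042, 0.33)

#: Default conductor boundary radii in cm (brain, CSF, skull, scalp
#: outer surfaces).  All default source shells lie inside the innermost
#: boundary.
DEFAULT_SHELL_RADII_CM = (8.4, 8.8, 9.2, 9.6)

_MU0_OVER_4PI = 1e-7  # T·m/A


class ConvergenceError(RuntimeError):
    """Raised when the Legendre series does not reach the requested tolerance."""


@dataclass(frozen=True)
class HeadModel:
    """Concentric 4-shell spherical volume conductor.

    ``shell_radii_cm`` are the outer radii of the brain, CSF, skull and
    scalp compartments; ``conductivities`` the matching values in S/m.
    EEG sensors are radially projected onto the scalp radius.
    """

    shell_radii_cm: tuple[float, float, float, float] = DEFAULT_SHELL_RADII_CM
    conductivities: tuple[float, float, float, float] = DEFAULT_CONDUCTIVITIES

    def __post_init__(self) -> None:
        r = self.shell_radii_cm
        if len(r) != 4 or any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("shell radii must be 4 strictly increasing values")
        if len(self.conductivities) != 4 or any(s <= 0 for s in self.conductivities):
            raise ValueError("need 4 positive conductivities")

    @property
    def scalp_radius_cm(self) -> float:
        return self.shell_radii_cm[-1]


@dataclass
class SourceModel:
    """Dipole grid on concentric spherical source shells."""

    radii_cm: tuple[float, ...]
    n_per_shell: int
    modality: str
    active_shells: tuple[float, ...]
    locations: np.ndarray = field(init=False)  # (n_loc, 3) cm
    orientations: np.ndarray = field(init=False)  # (n_loc, n_ori, 3)
    shell_of: np.ndarray = field(init=False)  # (n_loc,) shell radius per location

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.radii_cm, self.radii_cm[1:])):
            raise ValueError("shell radii must be strictly increasing")
        for r in self.active_shells:
            if r not in self.radii_cm:
                raise ValueError(
                    f"active shell {r} cm not among model radii {self.radii_cm}"
                )
        if self.modality not in ("eeg", "meg"):
            raise ValueError(f"unknown modality {self.modality!r}")
        dirs = equidistant_sphere_points(self.n_per_shell)
        locs, shells = [], []
        for r in self.active_shells:
            locs.append(dirs * r)
            shells.append(np.full(self.n_per_shell, float(r)))
        self.locations = np.concatenate(locs, axis=0)
        self.shell_of = np.concatenate(shells)
        frames = _orientation_frames(dirs)  # (n, 3, 3): azimuthal, polar, radial
        if self.modality == "meg":
            frames = frames[:, :2, :]
        self.orientations = np.tile(frames, (len(self.active_shells), 1, 1))

    @property
    def n_locations(self) -> int:
        return self.locations.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.orientations.shape[1]

    @property
    def n_columns(self) -> int:
        return self.n_locations * self.n_orientations


def _orientation_frames(dirs: np.ndarray) -> np.ndarray:
    """Orthonormal (azimuthal, polar, radial) frame per unit direction.

    At the poles the azimuth is undefined; the frame there falls back to
    the x/y axes, keeping the triad orthonormal.
    """
    x, y, z = dirs.T
    rho = np.hypot(x, y)
    cosphi = np.where(rho > 1e-12, x / np.where(rho > 1e-12, rho, 1.0), 1.0)
    sinphi = np.where(rho > 1e-12, y / np.where(rho > 1e-12, rho, 1.0), 0.0)
    costheta = z
    sintheta = rho
    azimuthal = np.column_stack([-sinphi, cosphi, np.zeros_like(z)])
    polar = np.column_stack([costheta * cosphi, costheta * sinphi, -sintheta])
    radial = dirs
    return np.stack([azimuthal, polar, radial], axis=1)


def build_source_model(
    radii_cm: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0),
    n_per_shell: int = 655,
    modality: str = "eeg",
    active_shells: tuple[float, ...] | None = None,
) -> SourceModel:
    """Construct the default concentric-shell dipole grid.

    By default the outer two shells (6 and 8 cm) are active jointly;
    pass a single radius to use one shell as the full source model.
    """
    radii_cm = tuple(float(r) for r in radii_cm)
    if active_shells is None:
        active_shells = radii_cm[-2:]
    else:
        active_shells = tuple(float(r) for r in active_shells)
    return SourceModel(
        radii_cm=radii_cm,
        n_per_shell=int(n_per_shell),
        modality=modality,
        active_shells=active_shells,
    )


@dataclass
class LeadField:
    """Linear map from source amplitudes to sensor measurements.

    ``matrix`` has shape ``(n_sensors, n_locations * n_orientations)``
    with orientations varying fastest.  EEG matrices are expressed in
    average reference, so every column sums to zero over sensors.
    """

    matrix: np.ndarray
    layout: SensorLayout
    model: SourceModel
    units: str
    head: HeadModel | None = None
    average_referenced: bool = False


# ---------------------------------------------------------------------------
# EEG kernel


@lru_cache(maxsize=16)
def _shell_gain_table(
    radii_m: tuple[float, ...], cond: tuple[float, ...], n_max: int
) -> np.ndarray:
    """Per-degree scalp gain of the layered conductor.

    For a source radial term ``r^-(n+1)`` (coefficient 1) in the inner
    compartment, returns ``gain[n]`` such that the scalp-surface radial
    function equals ``gain[n] * r1^-(n+1)`` where ``r1`` is the
    innermost boundary radius.  Solved per degree from interface
    continuity of potential and radial current plus the outer Neumann
    condition, with per-layer radius normalization for stability.
    """
    r1, r2, r3, r4 = radii_m
    s1, s2, s3, s4 = cond
    gains = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        A = np.zeros((7, 7))
        rhs = np.zeros(7)
        # unknowns: a1, a2, b2, a3, b3, a4, b4 with layer radial function
        # u_k(r) = a_k (r/r_k)^n + b_k (r_k/r)^(n+1); source term in layer 1
        # is (r1/r)^(n+1) after normalization.
        A[0, 0] = 1.0
        A[0, 1] = -((r1 / r2) ** n)
        A[0, 2] = -((r2 / r1) ** (n + 1))
        rhs[0] = -1.0
        A[1, 0] = s1 * n
        A[1, 1] = -s2 * n * (r1 / r2) ** n
        A[1, 2] = s2 * (n + 1) * (r2 / r1) ** (n + 1)
        rhs[1] = s1 * (n + 1)
        A[2, 1] = 1.0
        A[2, 2] = 1.0
        A[2, 3] = -((r2 / r3) ** n)
        A[2, 4] = -((r3 / r2) ** (n + 1))
        A[3, 1] = s2 * n
        A[3, 2] = -s2 * (n + 1)
        A[3, 3] = -s3 * n * (r2 / r3) ** n
        A[3, 4] = s3 * (n + 1) * (r3 / r2) ** (n + 1)
        A[4, 3] = 1.0
        A[4, 4] = 1.0
        A[4, 5] = -((r3 / r4) ** n)
        A[4, 6] = -((r4 / r3) ** (n + 1))
        A[5, 3] = s3 * n
        A[5, 4] = -s3 * (n + 1)
        A[5, 5] = -s4 * n * (r3 / r4) ** n
        A[5, 6] = s4 * (n + 1) * (r4 / r3) ** (n + 1)
        A[6, 5] = n
        A[6, 6] = -(n + 1)
        sol = np.linalg.solve(A, rhs)
        gains[n] = sol[5] + sol[6]
    return gains


def eeg_scalp_potential(
    sensor_dirs: np.ndarray,
    src_pos_cm: np.ndarray,
    src_ori: np.ndarray,
    head: HeadModel,
    n_max: int = 200,
    tol: float = 1e-6,
    degree_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Scalp potential of unit dipoles (1 nA·m) in the 4-shell conductor.

    Parameters
    ----------
    sensor_dirs
        ``(S, 3)`` unit vectors; sensors sit on the scalp sphere.
    src_pos_cm, src_ori
        ``(Q, 3)`` dipole positions (cm, inside the innermost boundary)
        and unit moments.
    degree_scale
        Optional per-degree multiplier (index = degree), e.g.
        ``-n(n+1)/R²`` to evaluate the surface Laplacian instead of the
        potential.
    tol
        Series truncation: stop once the maximum term magnitude falls
        below ``tol`` times the maximum accumulated value.

    Returns
    -------
    ``(S, Q)`` potentials in µV per nA·m (or scaled units under
    ``degree_scale``).
    """
    sensor_dirs = np.atleast_2d(np.asarray(sensor_dirs, dtype=float))
    src_pos_cm = np.atleast_2d(np.asarray(src_pos_cm, dtype=float))
    src_ori = np.atleast_2d(np.asarray(src_ori, dtype=float))
    radii_m = tuple(r / 100.0 for r in head.shell_radii_cm)
    r1 = radii_m[0]
    b = np.linalg.norm(src_pos_cm, axis=1) / 100.0  # m
    if np.any(b >= r1):
        raise ValueError(
            "source(s) outside the innermost conductor boundary "
            f"({head.shell_radii_cm[0]} cm)"
        )
    bdir = np.where(
        b[:, None] > 0, src_pos_cm / np.where(b[:, None] > 0, b[:, None] * 100.0, 1.0),
        np.array([0.0, 0.0, 1.0]),
    )
    gains = _shell_gain_table(radii_m, tuple(head.conductivities), n_max)

    t = sensor_dirs @ bdir.T  # (S, Q)
    qr = np.einsum("qi,qi->q", src_ori, bdir)  # (Q,)
    qs = sensor_dirs @ src_ori.T  # (S, Q)
    qtan = qs - t * qr[None, :]

    ratio = b / r1  # per source, < 1
    # running Legendre recurrences
    P_prev = np.ones_like(t)  # P_0
    P_cur = t.copy()  # P_1
    dP_prev = np.zeros_like(t)
    dP_cur = np.ones_like(t)
    pref = 1e-3 / (4.0 * np.pi * head.conductivities[0] * r1**2)  # nA·m -> µV
    V = np.zeros_like(t)
    rad_pow = np.ones_like(b)  # ratio^(n-1); 0^0 := 1 covers a central dipole
    converged = False
    for n in range(1, n_max + 1):
        if n > 1:
            P_new = ((2 * n - 1) * t * P_cur - (n - 1) * P_prev) / n
            dP_new = dP_prev + (2 * n - 1) * P_cur
            P_prev, P_cur = P_cur, P_new
            dP_prev, dP_cur = dP_cur, dP_new
            rad_pow = rad_pow * ratio
        scale = gains[n] * (degree_scale[n] if degree_scale is not None else 1.0)
        term = (pref * scale) * rad_pow[None, :] * (
            n * P_cur * qr[None, :] + dP_cur * qtan
        )
        V += term
        vmax = np.abs(V).max()
        if n > 5 and np.abs(term).max() < tol * max(vmax, 1e-300):
            converged = True
            break
    if not converged:
        achieved = np.abs(term).max() / max(np.abs(V).max(), 1e-300)
        raise ConvergenceError(
            f"Legendre series not converged at degree {n_max}: "
            f"achieved relative term size {achieved:.2e} > tol {tol:.2e}"
        )
    return V


def eeg_leadfield(
    layout: SensorLayout,
    model: SourceModel,
    head: HeadModel | None = None,
    n_max: int = 200,
    tol: float = 1e-6,
) -> LeadField:
    """EEG lead field in average reference, µV per nA·m.

    Sensor positions are radially projected onto the scalp sphere of the
    head model; their distance from that sphere only fixes the direction
    of each sensor.
    """
    if layout.modality != "eeg":
        raise ValueError("eeg_leadfield requires an EEG layout")
    head = head or HeadModel()
    dirs = layout.positions / np.linalg.norm(layout.positions, axis=1, keepdims=True)
    n_loc, n_ori = model.n_locations, model.n_orientations
    pos = np.repeat(model.locations, n_ori, axis=0)
    ori = model.orientations.reshape(n_loc * n_ori, 3)
    M = eeg_scalp_potential(dirs, pos, ori, head, n_max=n_max, tol=tol)
    M -= M.mean(axis=0, keepdims=True)
    return LeadField(
        matrix=M,
        layout=layout,
        model=model,
        units="uV/nAm",
        head=head,
        average_referenced=True,
    )


# ---------------------------------------------------------------------------
# MEG kernel (Sarvas closed form)


def meg_field(
    sens_pos_cm: np.ndarray,
    sens_ori: np.ndarray,
    src_pos_cm: np.ndarray,
    src_ori: np.ndarray,
) -> np.ndarray:
    """Magnetometer signal of unit dipoles (1 nA·m), fT per nA·m.

    Closed-form field of a current dipole in a spherically symmetric
    conductor centered at the origin, projected onto each coil normal.
    Returns ``(S, Q)``.
    """
    r = np.atleast_2d(np.asarray(sens_pos_cm, dtype=float)) / 100.0  # (S,3) m
    nrm = np.atleast_2d(np.asarray(sens_ori, dtype=float))
    r0 = np.atleast_2d(np.asarray(src_pos_cm, dtype=float)) / 100.0  # (Q,3)
    q = np.atleast_2d(np.asarray(src_ori, dtype=float)) * 1e-9  # A·m

    a_v = r[:, None, :] - r0[None, :, :]  # (S,Q,3)
    a = np.linalg.norm(a_v, axis=-1)  # (S,Q)
    rn = np.linalg.norm(r, axis=-1)  # (S,)
    if np.any(rn[:, None] <= np.linalg.norm(r0, axis=-1)[None, :]):
        raise ValueError("MEG sensor inside the source sphere")
    r0dotr = r @ r0.T  # (S,Q)
    adotr = np.einsum("sqi,si->sq", a_v, r)
    F = a * (rn[:, None] * a + rn[:, None] ** 2 - r0dotr)
    c1 = a**2 / rn[:, None] + adotr / a + 2.0 * a + 2.0 * rn[:, None]
    c2 = a + 2.0 * rn[:, None] + adotr / a
    gradF = c1[..., None] * r[:, None, :] - c2[..., None] * r0[None, :, :]
    qxr0 = np.cross(q, r0)  # (Q,3)
    proj = np.einsum("qi,si->sq", qxr0, r)  # (Q·r per sensor)
    B = (_MU0_OVER_4PI / F[..., None] ** 2) * (
        F[..., None] * qxr0[None, :, :] - proj[..., None] * gradF
    )
    return np.einsum("sqi,si->sq", B, nrm) * 1e15  # T -> fT


def meg_leadfield(layout: SensorLayout, model: SourceModel) -> LeadField:
    """MEG magnetometer lead field, fT per nA·m (tangential orientations)."""
    if layout.modality != "meg":
        raise ValueError("meg_leadfield requires an MEG layout")
    if model.modality != "meg":
        raise ValueError("source model must be built for MEG (no radial orientation)")
    n_loc, n_ori = model.n_locations, model.n_orientations
    pos = np.repeat(model.locations, n_ori, axis=0)
    ori = model.orientations.reshape(n_loc * n_ori, 3)
    M = meg_field(layout.positions, layout.orientations, pos, ori)
    return LeadField(matrix=M, layout=layout, model=model, units="fT/nAm")


# ---------------------------------------------------------------------------
# Arbitrary-dipole forward projection (used by the simulator)


def forward_dipoles(
    layout: SensorLayout,
    positions_cm: np.ndarray,
    moments_nAm: np.ndarray,
    head: HeadModel | None = None,
) -> np.ndarray:
    """Sensor signal of arbitrary dipoles: ``(n_sensors, n_dipoles)``.

    ``moments_nAm`` carries both orientation and strength (nA·m).  EEG
    output is average-referenced µV; MEG output fT.
    """
    positions_cm = np.atleast_2d(positions_cm)
    moments_nAm = np.atleast_2d(moments_nAm)
    if layout.modality == "eeg":
        head = head or HeadModel()
        dirs = layout.positions / np.linalg.norm(
            layout.positions, axis=1, keepdims=True
        )
        M = eeg_scalp_potential(dirs, positions_cm, moments_nAm, head)
        return M - M.mean(axis=0, keepdims=True)
    return meg_field(layout.positions, layout.orientations, positions_cm, moments_nAm)
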
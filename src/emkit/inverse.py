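"""L2 minimum-norm inverse, inverse–forward interpolation and CSD.

The inverse operator is the Tikhonov-regularized pseudoinverse
``W = Lᵀ (L Lᵀ + λ²_abs I)⁻¹`` of a lead field ``L``.  The
regularization parameter is specified on a relative, unit-free scale:
``λ_abs = λ · sqrt(trace(L Lᵀ) / n_sensors)``, i.e. relative to the RMS
singular value of the lead field, which makes the same λ usable for EEG
(µV) and MEG (fT) matrices.

Scalp interpolation and the current source density are both realized as
an inverse–forward pass: a minimum-norm fit of sources on the outermost
source shell explains the measured topography, and the fitted sources
are projected forward either to new sensor positions (interpolation) or
through the per-degree surface-Laplacian kernel (CSD).  Spatial
smoothness is therefore governed by the physical lead field and the
regularization strength rather than by an abstract spline order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import SensorLayout
from .forward import (
    HeadModel,
    LeadField,
    SourceModel,
    build_source_model,
    eeg_scalp_potential,
    meg_field,
    meg_leadfield,
)

__all__ = [
    "InverseOperator",
    "SourceEstimate",
    "build_inverse",
    "apply_inverse",
    "interpolate_map",
    "csd_map",
    "InterpolationOperator",
]


@dataclass
class InverseOperator:
    """Minimum-norm estimator ``(n_locations·n_orientations) × n_sensors``."""

    matrix: np.ndarray
    lam: float  # relative Tikhonov parameter
    lam_abs: float  # absolute value actually used
    model: SourceModel


@dataclass
class SourceEstimate:
    """Source amplitudes and per-location orientation power over time."""

    amplitudes: np.ndarray  # (n_locations, n_orientations, n_times), nA·m
    power: np.ndarray  # (n_locations, n_times), Euclidean norm over orientations
    model: SourceModel


def _lambda_abs(L: np.ndarray, lam: float) -> float:
    return lam * np.sqrt(np.trace(L @ L.T) / L.shape[0])


def build_inverse(leadfield: LeadField, lam: float) -> InverseOperator:
    """Tikhonov-regularized L2 minimum-norm operator.

    Parameters
    ----------
    leadfield
        Forward model ``L`` (sensors × source columns).
    lam
        Regularization parameter on the relative scale described in the
        module docstring; must be ≥ 0.  With ``lam = 0`` the lead field
        must have full sensor rank.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    L = leadfield.matrix
    lam_abs = _lambda_abs(L, lam)
    gram = L @ L.T + lam_abs**2 * np.eye(L.shape[0])
    try:
        cho = scipy.linalg.cho_factor(gram)
        W = scipy.linalg.cho_solve(cho, L).T
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sensor covariance is singular; use lambda > 0 with a "
            "rank-deficient lead field (e.g. average-referenced EEG)"
        ) from exc
    return InverseOperator(
        matrix=W, lam=lam, lam_abs=lam_abs, model=leadfield.model
    )


def apply_inverse(operator: InverseOperator, data: np.ndarray) -> SourceEstimate:
    """Estimate source amplitudes for ``data`` (n_sensors × n_times).

    ``power`` is the Euclidean norm over the orientations at each
    location and time, a non-negative measure of local source strength.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] != operator.matrix.shape[1]:
        raise ValueError(
            f"data has {data.shape[0]} channels, operator expects "
            f"{operator.matrix.shape[1]}"
        )
    amps = operator.matrix @ data
    model = operator.model
    amps = amps.reshape(model.n_locations, model.n_orientations, -1)
    power = np.linalg.norm(amps, axis=1)
    return SourceEstimate(amplitudes=amps, power=power, model=model)


class InterpolationOperator:
    """Reusable inverse–forward interpolator for one sensor layout.

    Builds the lead field of the outermost source shell once; the
    ``interpolate``/``csd`` methods then only do small linear solves.
    Supports per-call sensor subsets and per-sensor reliability weights
    (inverse-variance weighting of the minimum-norm fit), which is what
    the artifact-repair stage needs.
    """

    def __init__(
        self,
        layout: SensorLayout,
        lam: float = 0.05,
        n_sources: int = 655,
        source_radius_cm: float | None = None,
        head: HeadModel | None = None,
    ):
        self.layout = layout
        self.lam = lam
        self.head = head or HeadModel()
        if source_radius_cm is None:
            source_radius_cm = 8.0
        self.model = build_source_model(
            n_per_shell=n_sources,
            modality=layout.modality,
            active_shells=(source_radius_cm,),
            radii_cm=(2.0, 4.0, 6.0, source_radius_cm),
        )
        if layout.modality == "eeg":
            dirs = layout.positions / np.linalg.norm(
                layout.positions, axis=1, keepdims=True
            )
            pos = np.repeat(self.model.locations, self.model.n_orientations, axis=0)
            ori = self.model.orientations.reshape(-1, 3)
            self._L_raw = eeg_scalp_potential(dirs, pos, ori, self.head)
            self._csd_scale = None  # computed lazily
        else:
            self._L_raw = meg_leadfield(layout, self.model).matrix

    def _solve(
        self,
        values: np.ndarray,
        good: np.ndarray,
        weights: np.ndarray | None,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Weighted minimum-norm source fit from the good sensors.

        Returns source amplitudes and, for EEG, the reference offset of
        the good-sensor average so forward projections stay consistent.
        """
        L = self._L_raw[good]
        ref = None
        self._input_offset = 0.0
        if self.layout.modality == "eeg":
            # reference fit and data to the good-sensor mean; the offset is
            # restored on prediction so the caller's reference is preserved
            ref = L.mean(axis=0, keepdims=True)
            L = L - ref
            self._input_offset = values.mean(axis=0, keepdims=True)
            values = values - self._input_offset
        if weights is None:
            w = np.ones(L.shape[0])
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (L.shape[0],) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per good sensor")
        sw = np.sqrt(w)
        Lw = sw[:, None] * L
        vw = sw[:, None] * values
        lam_abs = _lambda_abs(Lw, self.lam)
        gram = Lw @ Lw.T + lam_abs**2 * np.eye(Lw.shape[0])
        j = Lw.T @ np.linalg.solve(gram, vw)
        return j, ref

    def interpolate(
        self,
        values: np.ndarray,
        targets: np.ndarray | None = None,
        good: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ) -> np.ndarray:
        """Interpolate sensor values to target positions.

        Parameters
        ----------
        values
            ``(n_good, ...)`` measured values on the good sensors.
        targets
            ``(T, 3)`` positions (cm); defaults to the full layout.
        good
            Boolean mask or index array over layout sensors from which
            ``values`` were taken; defaults to all sensors.
        weights
            Optional non-negative reliability weight per good sensor.
        """
        values = np.asarray(values, dtype=float)
        squeeze = values.ndim == 1
        if squeeze:
            values = values[:, None]
        if good is None:
            good = np.ones(self.layout.n_sensors, dtype=bool)
        good = np.asarray(good)
        n_good = int(good.sum()) if good.dtype == bool else len(good)
        if n_good < 4:
            raise ValueError("interpolation needs at least 4 good sensors")
        if values.shape[0] != n_good:
            raise ValueError("values must match the number of good sensors")
        j, ref = self._solve(values, good, weights)
        if targets is None:
            L_t = self._L_raw
        else:
            targets = np.atleast_2d(np.asarray(targets, dtype=float))
            if self.layout.modality == "eeg":
                dirs = targets / np.linalg.norm(targets, axis=1, keepdims=True)
                pos = np.repeat(
                    self.model.locations, self.model.n_orientations, axis=0
                )
                ori = self.model.orientations.reshape(-1, 3)
                L_t = eeg_scalp_potential(dirs, pos, ori, self.head)
            else:
                tdirs = targets / np.linalg.norm(targets, axis=1, keepdims=True)
                pos = np.repeat(
                    self.model.locations, self.model.n_orientations, axis=0
                )
                ori = self.model.orientations.reshape(-1, 3)
                L_t = meg_field(targets, tdirs, pos, ori)
        if ref is not None:
            L_t = L_t - ref
        out = L_t @ j + self._input_offset
        return out[:, 0] if squeeze else out

    def csd(self, values: np.ndarray, good: np.ndarray | None = None) -> np.ndarray:
        """Current source density at the layout sensors, µV/cm².

        The minimum-norm potential fit is re-expanded with each Legendre
        degree ``n`` scaled by ``-n(n+1)/R²`` (the angular Laplacian on
        the scalp sphere of radius R).
        """
        if self.layout.modality != "eeg":
            raise ValueError("CSD is defined for EEG scalp potentials only")
        values = np.asarray(values, dtype=float)
        squeeze = values.ndim == 1
        if squeeze:
            values = values[:, None]
        if good is None:
            good = np.ones(self.layout.n_sensors, dtype=bool)
        j, _ = self._solve(values, good, None)
        L_csd = self._csd_leadfield()
        out = L_csd @ j
        return out[:, 0] if squeeze else out

    def _csd_leadfield(self) -> np.ndarray:
        if getattr(self, "_L_csd", None) is None:
            R = self.head.scalp_radius_cm
            n = np.arange(0, 401, dtype=float)
            scale = -n * (n + 1) / R**2
            dirs = self.layout.positions / np.linalg.norm(
                self.layout.positions, axis=1, keepdims=True
            )
            pos = np.repeat(self.model.locations, self.model.n_orientations, axis=0)
            ori = self.model.orientations.reshape(-1, 3)
            # The Laplacian amplifies high degrees by n(n+1); evaluate with a
            # deeper series and absolute-style tolerance guarded by n_max.
            self._L_csd = eeg_scalp_potential(
                dirs, pos, ori, self.head, n_max=400, tol=1e-8, degree_scale=scale
            )
        return self._L_csd


def interpolate_map(
    values: np.ndarray,
    layout: SensorLayout,
    target_points: np.ndarray | None = None,
    lam: float = 0.05,
    weights: np.ndarray | None = None,
    good: np.ndarray | None = None,
    head: HeadModel | None = None,
    n_sources: int = 655,
) -> np.ndarray:
    """One-shot inverse–forward interpolation (see InterpolationOperator)."""
    op = InterpolationOperator(layout, lam=lam, n_sources=n_sources, head=head)
    return op.interpolate(values, targets=target_points, good=good, weights=weights)


def csd_map(
    values: np.ndarray,
    layout: SensorLayout,
    lam: float = 0.05,
    head: HeadModel | None = None,
    n_sources: int = 655,
) -> np.ndarray:
    """One-shot current source density map at the sensors, µV/cm²."""
    op = InterpolationOperator(layout, lam=lam, n_sources=n_sources, head=head)
    return op.csd(values)
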
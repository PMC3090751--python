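"""Core in-memory containers for continuous, epoched, and averaged data.

Conventions used throughout the package:

* Head-centered Cartesian coordinates in cm: x points to the subject's
  right, y anterior, z superior.
* Sample indices are 0-based; the time of sample ``i`` in an epoch is
  ``t0 + i / fs`` seconds, with negative times pre-stimulus.
* EEG data are in microvolts, MEG magnetometer data in femtotesla.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SensorLayout",
    "ContinuousRecording",
    "TriggerTable",
    "ConditionTable",
    "EpochSet",
    "EvokedAverage",
]


@dataclass
class SensorLayout:
    """Sensor names and 3D positions for one recording modality.

    Parameters
    ----------
    names
        Unique channel labels, one per sensor.
    positions
        ``(n_sensors, 3)`` head-centered coordinates in cm.
    modality
        ``"eeg"`` or ``"meg"`` (magnetometers).
    reference_name
        Label of the recording reference electrode, or ``"none"`` (MEG,
        or reference-free data).
    orientations
        ``(n_sensors, 3)`` unit coil normals; required for MEG.
    """

    names: list[str]
    positions: np.ndarray
    modality: str = "eeg"
    reference_name: str = "none"
    orientations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_sensors, 3)")
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("number of names must match rows of positions")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.modality not in ("eeg", "meg"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "meg":
            if self.orientations is None:
                raise ValueError("MEG layouts require coil orientations")
            self.orientations = np.asarray(self.orientations, dtype=float)
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("MEG orientations must be unit vectors")

    @property
    def n_sensors(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"sensor {name!r} not in layout; available: {self.names}"
            ) from None

    def subset(self, keep: Sequence[int]) -> "SensorLayout":
        keep = list(keep)
        return SensorLayout(
            names=[self.names[i] for i in keep],
            positions=self.positions[keep],
            modality=self.modality,
            reference_name=self.reference_name,
            orientations=None if self.orientations is None else self.orientations[keep],
        )

    @property
    def head_radius(self) -> float:
        """Largest sensor distance from the head center, in cm."""
        return float(np.max(np.linalg.norm(self.positions, axis=1)))


@dataclass
class ContinuousRecording:
    """Continuous multi-channel recording with a parallel trigger sequence."""

    data: np.ndarray  # (n_channels, n_samples), physical units
    fs: float
    layout: SensorLayout
    status: np.ndarray | None = None  # (n_samples,) integer trigger values

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != self.layout.n_sensors:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but layout has "
                f"{self.layout.n_sensors} sensors"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.status is not None:
            self.status = np.asarray(self.status)
            if self.status.shape != (self.data.shape[1],):
                raise ValueError("status must have one value per sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TriggerTable:
    """Trigger events as (sample_index, code) pairs, chronologically ordered."""

    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = [s for s, _ in self.events]
        if any(s2 <= s1 for s1, s2 in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if any(c == 0 for _, c in self.events):
            raise ValueError("event codes must be nonzero")

    def __len__(self) -> int:
        return len(self.events)

    def select(self, codes: Sequence[int]) -> "TriggerTable":
        codes = set(codes)
        return TriggerTable([(s, c) for s, c in self.events if c in codes])


@dataclass
class ConditionTable:
    """Per-trial condition codes and inclusion flags.

    Stored as parallel arrays; ``trial_index`` must cover 0..n-1 exactly
    once so the table can be hand-edited and re-read safely.
    """

    trial_index: np.ndarray
    code: np.ndarray
    include: np.ndarray

    def __post_init__(self) -> None:
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        self.code = np.asarray(self.code, dtype=int)
        self.include = np.asarray(self.include, dtype=bool)
        n = len(self.trial_index)
        if len(self.code) != n or len(self.include) != n:
            raise ValueError("condition table columns must have equal length")
        if sorted(self.trial_index.tolist()) != list(range(n)):
            raise ValueError("trial_index must cover 0..n-1 exactly once")

    @classmethod
    def from_codes(cls, codes: Sequence[int]) -> "ConditionTable":
        codes = np.asarray(codes, dtype=int)
        return cls(np.arange(len(codes)), codes, np.ones(len(codes), dtype=bool))

    def __len__(self) -> int:
        return len(self.trial_index)

    def copy(self) -> "ConditionTable":
        return ConditionTable(
            self.trial_index.copy(), self.code.copy(), self.include.copy()
        )


@dataclass
class EpochSet:
    """Epoched data: trials x channels x samples plus condition bookkeeping."""

    data: np.ndarray
    fs: float
    t0: float  # time of first sample relative to the trigger, in s
    layout: SensorLayout
    conditions: ConditionTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != self.layout.n_sensors:
            raise ValueError("channel count must match layout")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("condition table must have one row per trial")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), conditions=self.conditions.copy())


@dataclass
class EvokedAverage:
    """Condition average with per-sensor interpolation bookkeeping."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    t0: float
    layout: SensorLayout
    condition_code: int
    n_trials_used: int
    interpolation_counts: np.ndarray | None = None  # per sensor

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.layout.n_sensors:
            raise ValueError("data must be (n_channels, n_samples) matching layout")
        if self.n_trials_used < 1:
            raise ValueError("an average must use at least one trial")
        if self.interpolation_counts is None:
            self.interpolation_counts = np.zeros(self.layout.n_sensors, dtype=int)
        else:
            self.interpolation_counts = np.asarray(self.interpolation_counts, dtype=int)
            if np.any(self.interpolation_counts > self.n_trials_used):
                raise ValueError("interpolation counts cannot exceed n_trials_used")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.fs
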
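"""Statistical control of artifacts (SCADS) on epoched data.

Per trial and sensor, three distributional statistics are computed:
absolute maximum amplitude, standard deviation over time, and absolute
maximum temporal gradient.  Robust thresholds (median + k·IQR) derived
from those distributions flag sensor-specific and global artifacts.
Each trial then falls into exactly one of three scenarios: clean (all
sensors fine, averaged as-is), repaired (contaminated sensors replaced
by weighted inverse–forward interpolation from the clean ones, then
averaged), or rejected (too many or too clustered bad sensors for a
trustworthy interpolation).

For average-reference EEG, detection runs twice: first in the recording
reference, so sensor-specific artifacts cannot leak into every channel
through the average; then, after repairing those sensors and
re-referencing to the average, a second pass exposes global artifacts
with the reference bias removed.  MEG and single-reference EEG use one
pass.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import EpochSet, EvokedAverage, SensorLayout
from .forward import forward_dipoles
from .inverse import InterpolationOperator

logger = logging.getLogger(__name__)

__all__ = [
    "TrialSensorStats",
    "ThresholdSet",
    "ArtifactFlags",
    "compute_trial_stats",
    "propose_thresholds",
    "write_thresholds",
    "read_thresholds",
    "flag_artifacts",
    "interpolation_feasibility",
    "apply_feasibility",
    "two_pass_detect",
    "repair_and_average",
    "scenario_counts",
]

STAT_NAMES = ("amp_max", "sd", "grad_max")


@dataclass
class TrialSensorStats:
    """Per-trial, per-sensor artifact statistics (all non-negative)."""

    amp_max: np.ndarray  # (n_trials, n_channels)
    sd: np.ndarray
    grad_max: np.ndarray
    per_interval: dict | None = None  # stat name -> (n_intervals, trials, channels)

    def get(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def n_trials(self) -> int:
        return self.amp_max.shape[0]

    @property
    def n_channels(self) -> int:
        return self.amp_max.shape[1]


@dataclass
class ThresholdSet:
    """Per-channel and global (across-channel) upper limits per statistic."""

    channel_limits: dict  # stat -> (n_channels,) array
    global_limits: dict  # stat -> float
    max_bad_sensors_per_trial: int
    k: float
    feasibility_epsilon: float = 0.2
    feasibility_phi: float = 0.1


@dataclass
class ArtifactFlags:
    sensor_bad: np.ndarray  # (n_trials, n_channels) bool
    trial_rejected: np.ndarray  # (n_trials,) bool
    reasons: dict = field(default_factory=dict)  # trial -> list of reason codes

    def add_reason(self, trial: int, reason: str) -> None:
        self.reasons.setdefault(int(trial), [])
        if reason not in self.reasons[int(trial)]:
            self.reasons[int(trial)].append(reason)

    def union(self, other: "ArtifactFlags") -> "ArtifactFlags":
        merged = ArtifactFlags(
            sensor_bad=self.sensor_bad | other.sensor_bad,
            trial_rejected=self.trial_rejected | other.trial_rejected,
            reasons={k: list(v) for k, v in self.reasons.items()},
        )
        for t, rs in other.reasons.items():
            for r in rs:
                merged.add_reason(t, r)
        return merged


def compute_trial_stats(
    epochs: EpochSet, intervals: list[tuple[float, float]] | None = None
) -> TrialSensorStats:
    """Compute amplitude / SD / gradient statistics per trial and sensor.

    With ``intervals`` (in seconds relative to the trigger), statistics
    are computed inside each interval and the per-interval maxima are
    used for thresholding; the raw per-interval values are kept.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    times = epochs.times

    def one(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        amp = np.abs(data).max(axis=2)
        sd = data.std(axis=2, ddof=1) if data.shape[2] > 1 else np.zeros(data.shape[:2])
        grad = (
            np.abs(np.diff(data, axis=2)).max(axis=2)
            if data.shape[2] > 1
            else np.zeros(data.shape[:2])
        )
        return amp, sd, grad

    if intervals is None:
        amp, sd, grad = one(epochs.data)
        return TrialSensorStats(amp_max=amp, sd=sd, grad_max=grad)
    per = {name: [] for name in STAT_NAMES}
    for lo, hi in intervals:
        sel = (times >= lo) & (times <= hi)
        if not sel.any():
            raise ValueError(f"interval ({lo}, {hi}) s lies outside the epoch")
        amp, sd, grad = one(epochs.data[:, :, sel])
        per["amp_max"].append(amp)
        per["sd"].append(sd)
        per["grad_max"].append(grad)
    stacked = {k: np.stack(v) for k, v in per.items()}
    return TrialSensorStats(
        amp_max=stacked["amp_max"].max(axis=0),
        sd=stacked["sd"].max(axis=0),
        grad_max=stacked["grad_max"].max(axis=0),
        per_interval=stacked,
    )


def _iqr(x: np.ndarray, axis=0) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25], axis=axis)
    return q75 - q25


def propose_thresholds(
    stats: TrialSensorStats,
    k: float = 3.0,
    max_bad_fraction: float = 0.1,
    relative_floor: float = 0.35,
    feasibility_epsilon: float = 0.2,
    feasibility_phi: float = 0.1,
) -> ThresholdSet:
    """Robust automatic thresholds: median + k·max(IQR, floor·median).

    Per channel, the limit for each statistic comes from its
    distribution over trials; the global limit comes from the
    distribution of each trial's across-channel median.  The spread term
    is floored at ``relative_floor`` times the median: per-trial maximum
    statistics are extreme-value distributed, and a pure IQR spread
    underestimates their tail enough to flag a percent of perfectly
    clean sensor-trials.  The floor sets the smallest deviation treated
    as artifactual to ``k·relative_floor`` of the typical statistic
    (``relative_floor=0`` restores the pure IQR rule).  The result is
    meant to be written to a text file, reviewed, possibly hand-edited,
    and re-read.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if stats.n_trials < 4:
        raise ValueError("threshold proposal needs at least 4 trials")
    channel_limits, global_limits = {}, {}
    for name in STAT_NAMES:
        x = stats.get(name)
        med = np.median(x, axis=0)
        spread = np.maximum(_iqr(x, axis=0), relative_floor * med)
        channel_limits[name] = med + k * spread
        g = np.median(x, axis=1)  # per-trial across-channel statistic
        gmed = np.median(g)
        global_limits[name] = float(
            gmed + k * max(_iqr(g), relative_floor * gmed)
        )
    return ThresholdSet(
        channel_limits=channel_limits,
        global_limits=global_limits,
        max_bad_sensors_per_trial=int(np.ceil(max_bad_fraction * stats.n_channels)),
        k=k,
        feasibility_epsilon=feasibility_epsilon,
        feasibility_phi=feasibility_phi,
    )


def write_thresholds(
    thresholds: ThresholdSet, path: str | os.PathLike, channel_names=None
) -> None:
    lines = [
        "# channel stat limit   (editable; GLOBAL rows are across-channel limits)",
        f"PARAM k {thresholds.k:g}",
        f"PARAM max_bad_sensors_per_trial {thresholds.max_bad_sensors_per_trial}",
        f"PARAM feasibility_epsilon {thresholds.feasibility_epsilon:g}",
        f"PARAM feasibility_phi {thresholds.feasibility_phi:g}",
    ]
    n = len(next(iter(thresholds.channel_limits.values())))
    names = channel_names or [f"ch{i}" for i in range(n)]
    for stat in STAT_NAMES:
        for i in range(n):
            lines.append(f"{names[i]} {stat} {float(thresholds.channel_limits[stat][i])!r}")
        lines.append(f"GLOBAL {stat} {float(thresholds.global_limits[stat])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_thresholds(
    path: str | os.PathLike, channel_names=None
) -> ThresholdSet:
    params = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "PARAM":
            params[parts[1]] = float(parts[2])
            continue
        rows.append((parts[0], parts[1], float(parts[2])))
    names = channel_names or sorted(
        {r[0] for r in rows if r[0] != "GLOBAL"},
        key=[r[0] for r in rows].index,
    )
    channel_limits = {
        stat: np.array(
            [next(v for c, s, v in rows if c == n and s == stat) for n in names]
        )
        for stat in STAT_NAMES
    }
    global_limits = {
        stat: next(v for c, s, v in rows if c == "GLOBAL" and s == stat)
        for stat in STAT_NAMES
    }
    return ThresholdSet(
        channel_limits=channel_limits,
        global_limits=global_limits,
        max_bad_sensors_per_trial=int(params.get("max_bad_sensors_per_trial", 1)),
        k=params.get("k", 3.0),
        feasibility_epsilon=params.get("feasibility_epsilon", 0.2),
        feasibility_phi=params.get("feasibility_phi", 0.1),
    )


def flag_artifacts(stats: TrialSensorStats, thresholds: ThresholdSet) -> ArtifactFlags:
    """Apply thresholds: sensor flags plus provisional global rejections.

    A sensor-trial is bad when any statistic exceeds its per-channel
    limit; a trial is provisionally rejected when its across-channel
    statistic exceeds the global limit or too many of its sensors are
    bad (the interpolation feasibility test may still reprieve or
    confirm it later).
    """
    sensor_bad = np.zeros((stats.n_trials, stats.n_channels), dtype=bool)
    flags = ArtifactFlags(
        sensor_bad=sensor_bad,
        trial_rejected=np.zeros(stats.n_trials, dtype=bool),
    )
    for name in STAT_NAMES:
        x = stats.get(name)
        sensor_bad |= x > thresholds.channel_limits[name][None, :]
        g = np.median(x, axis=1)
        over = g > thresholds.global_limits[name]
        flags.trial_rejected |= over
        for t in np.nonzero(over)[0]:
            flags.add_reason(t, f"global_{name}")
    too_many = sensor_bad.sum(axis=1) > thresholds.max_bad_sensors_per_trial
    flags.trial_rejected |= too_many
    for t in np.nonzero(too_many)[0]:
        flags.add_reason(t, "too_many_bad_sensors")
    flags.sensor_bad = sensor_bad
    return flags


def interpolation_feasibility(
    bad_sensors: np.ndarray,
    layout: SensorLayout,
    epsilon: float = 0.2,
    phi: float = 0.1,
    depth_fraction: float = 0.8,
    lam: float = 0.05,
    interp: InterpolationOperator | None = None,
) -> tuple[bool, float]:
    """Can the bad sensors be interpolated from the remaining ones?

    One synthetic test topography per sensor is generated: the forward
    field of a unit source directly beneath that sensor at
    ``depth_fraction`` of the head radius (a peaked, sensor-specific
    map).  Each topography is reconstructed at the bad sensors from the
    good ones; the feasibility test passes when the fraction of
    topographies with relative RMS reconstruction error above
    ``epsilon`` is at most ``phi``.

    Returns ``(passed, worst_error)``.
    """
    bad = np.asarray(bad_sensors, dtype=bool)
    good = ~bad
    if good.sum() < 4:
        return False, np.inf
    if not bad.any():
        return True, 0.0
    topos = _feasibility_topographies(layout, depth_fraction)
    interp = interp or InterpolationOperator(layout, lam=lam)
    recon = interp.interpolate(topos[good], targets=layout.positions[bad], good=good)
    true = topos[bad]
    num = np.sqrt(np.mean((recon - true) ** 2, axis=0))
    # normalize by each topography's overall scale: a peaked map carries
    # near-zero signal at distant sensors, so normalizing by the deleted
    # subset alone would declare trivially small absolute errors infeasible
    den = np.sqrt(np.mean(topos**2, axis=0))
    errors = num / np.where(den > 0, den, 1.0)
    worst = float(errors.max())
    passed = np.mean(errors > epsilon) <= phi
    return bool(passed), worst


_topo_cache: dict = {}


def _feasibility_topographies(layout: SensorLayout, depth_fraction: float) -> np.ndarray:
    key = (id(layout), depth_fraction)
    if key not in _topo_cache:
        dirs = layout.positions / np.linalg.norm(layout.positions, axis=1, keepdims=True)
        r = depth_fraction * layout.head_radius
        if layout.modality == "eeg":
            moments = dirs * 10.0  # radial unit sources, nA·m
        else:
            # radial sources are silent in MEG; use a tangential moment
            up = np.array([0.0, 0.0, 1.0])
            tang = np.cross(dirs, up)
            nrm = np.linalg.norm(tang, axis=1, keepdims=True)
            tang = np.where(nrm > 1e-6, tang / np.where(nrm > 1e-6, nrm, 1), [1.0, 0, 0])
            moments = tang * 10.0
        _topo_cache[key] = forward_dipoles(layout, dirs * r, moments)
    return _topo_cache[key]


def apply_feasibility(
    flags: ArtifactFlags,
    layout: SensorLayout,
    thresholds: ThresholdSet,
    interp: InterpolationOperator | None = None,
) -> ArtifactFlags:
    """Reject trials whose bad-sensor pattern fails the feasibility test."""
    interp = interp or InterpolationOperator(layout)
    out = ArtifactFlags(
        sensor_bad=flags.sensor_bad.copy(),
        trial_rejected=flags.trial_rejected.copy(),
        reasons={k: list(v) for k, v in flags.reasons.items()},
    )
    patterns: dict[bytes, bool] = {}
    for t in range(flags.sensor_bad.shape[0]):
        if out.trial_rejected[t] or not flags.sensor_bad[t].any():
            continue
        key = flags.sensor_bad[t].tobytes()
        if key not in patterns:
            ok, _ = interpolation_feasibility(
                flags.sensor_bad[t],
                layout,
                epsilon=thresholds.feasibility_epsilon,
                phi=thresholds.feasibility_phi,
                interp=interp,
            )
            patterns[key] = ok
        if not patterns[key]:
            out.trial_rejected[t] = True
            out.add_reason(t, "interpolation_infeasible")
    return out


def two_pass_detect(
    epochs: EpochSet,
    k: float = 3.0,
    mode: str = "average-ref",
    max_bad_fraction: float = 0.1,
    interp: InterpolationOperator | None = None,
) -> tuple[ArtifactFlags, ThresholdSet]:
    """Artifact detection with two-pass referencing for average-ref EEG.

    Pass 1 works in the recording reference, isolating sensor-specific
    artifacts before they can contaminate every channel through the
    average.  Flagged sensors are interpolated, the data re-referenced
    to the average, and pass 2 re-derives thresholds and flags on the
    re-referenced data, exposing global artifacts.  The returned flags
    are the union of both passes.  MEG and single-reference analyses
    (``mode="single"``) run one pass only.
    """
    stats1 = compute_trial_stats(epochs)
    thr1 = propose_thresholds(stats1, k=k, max_bad_fraction=max_bad_fraction)
    flags1 = flag_artifacts(stats1, thr1)
    if mode == "single" or epochs.layout.modality == "meg":
        return flags1, thr1
    if mode != "average-ref":
        raise ValueError("mode must be 'average-ref' or 'single'")

    interp = interp or InterpolationOperator(epochs.layout)
    repaired = epochs.copy()
    for t in range(epochs.n_trials):
        bad = flags1.sensor_bad[t]
        if not bad.any() or (~bad).sum() < 4:
            continue
        good = ~bad
        repaired.data[t, bad, :] = interp.interpolate(
            repaired.data[t, good, :],
            targets=epochs.layout.positions[bad],
            good=good,
        )
    avg = repaired.data.mean(axis=1, keepdims=True)
    repaired.data = repaired.data - avg

    stats2 = compute_trial_stats(repaired)
    thr2 = propose_thresholds(stats2, k=k, max_bad_fraction=max_bad_fraction)
    flags2 = flag_artifacts(stats2, thr2)
    return flags1.union(flags2), thr2


def repair_and_average(
    epochs: EpochSet,
    flags: ArtifactFlags,
    weights: np.ndarray | None = None,
    stats: TrialSensorStats | None = None,
    lam: float = 0.05,
    interp: InterpolationOperator | None = None,
    return_repaired: bool = False,
):
    """Interpolate bad sensors on retained trials and average by condition.

    Contributing sensors are weighted by ``w = 1 / (1 + z)`` where ``z``
    is the sensor's standardized noise statistic (robust z-score of its
    SD within the trial's distribution): noisier sensors influence the
    interpolation fit less.  Conditions whose trials were all rejected
    are skipped with a logged warning.

    Returns a list of :class:`EvokedAverage` (and the repaired single-
    trial EpochSet when ``return_repaired`` is set).
    """
    if weights is None and stats is not None:
        med = np.median(stats.sd, axis=0)
        iqr = _iqr(stats.sd, axis=0)
        z = (stats.sd - med[None, :]) / (iqr[None, :] + 1e-12)
        weights = 1.0 / (1.0 + np.clip(z, 0.0, None))
    repaired = epochs.copy()
    interp_count_by_code: dict[int, np.ndarray] = {}
    interp = interp or (
        InterpolationOperator(epochs.layout, lam=lam)
        if flags.sensor_bad.any()
        else None
    )
    for t in range(epochs.n_trials):
        if flags.trial_rejected[t]:
            continue
        bad = flags.sensor_bad[t]
        if not bad.any():
            continue
        good = ~bad
        w = weights[t, good] if weights is not None else None
        repaired.data[t, bad, :] = interp.interpolate(
            repaired.data[t, good, :],
            targets=epochs.layout.positions[bad],
            good=good,
            weights=w,
        )

    averages = []
    cond = epochs.conditions
    for code in np.unique(cond.code):
        rows = np.nonzero(
            (cond.code == code) & cond.include & ~flags.trial_rejected
        )[0]
        if len(rows) == 0:
            logger.warning("condition %d has no surviving trials; skipped", code)
            continue
        counts = flags.sensor_bad[rows].sum(axis=0)
        averages.append(
            EvokedAverage(
                data=repaired.data[rows].mean(axis=0),
                fs=epochs.fs,
                t0=epochs.t0,
                layout=epochs.layout,
                condition_code=int(code),
                n_trials_used=len(rows),
                interpolation_counts=counts,
            )
        )
    if return_repaired:
        return averages, repaired
    return averages


def scenario_counts(flags: ArtifactFlags) -> dict:
    """Trial trichotomy: clean / repaired / rejected counts (sum = n_trials)."""
    rejected = flags.trial_rejected
    repaired = ~rejected & flags.sensor_bad.any(axis=1)
    clean = ~rejected & ~flags.sensor_bad.any(axis=1)
    return {
        "clean": int(clean.sum()),
        "repaired": int(repaired.sum()),
        "rejected": int(rejected.sum()),
    }
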
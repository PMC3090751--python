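"""Synthetic EEG/MEG generation from known dipole sources.

Every fixture and method test in the package can be produced here
without any recorded data: dipoles with configurable waveforms are
projected through the spherical forward models and mixed with four
noise classes —

* white: independent Gaussian noise per sensor and sample;
* temporally correlated: an AR(1) process sharing one random spatial
  topography across the dataset;
* sensor noise: independent per-sensor noise with per-sensor random
  amplitudes (some sensors noisier than others);
* brain noise: fresh random dipoles per trial projected through the
  lead field, giving spatially correlated background activity —

plus simulated ocular artifacts (Poisson-timed raised-cosine blinks
driven by a pair of dipoles near the eyes, loading mostly on frontal
sensors).

All randomness flows from one mandatory seed through numpy's PCG64
generator, so identical configurations reproduce identical data on any
platform.  A GroundTruth record stores every drawn parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .containers import ConditionTable, EpochSet, EvokedAverage, SensorLayout
from .forward import HeadModel, forward_dipoles
from .spherical import spherical_cap_points

__all__ = [
    "SimSource",
    "NoiseSpec",
    "SimConfig",
    "GroundTruth",
    "make_layout",
    "waveform",
    "simulate",
    "vary_across",
]


def make_layout(kind: str, n: int) -> SensorLayout:
    """Deterministic whole-head sensor layouts for simulation.

    ``sphere_eeg``: n electrodes on the upper 3/4 of an 8 cm scalp
    sphere; the sensor closest to the vertex is named Cz and acts as the
    recording reference.  ``sphere_meg``: n radial magnetometers on a
    10 cm helmet sphere.
    """
    if n < 8:
        raise ValueError("layouts need at least 8 sensors")
    dirs = spherical_cap_points(n, -0.5)
    if kind == "sphere_eeg":
        positions = dirs * 8.0
        names = [f"E{i + 1}" for i in range(n)]
        vertex = int(np.argmax(dirs[:, 2]))
        names[vertex] = "Cz"
        return SensorLayout(names, positions, "eeg", reference_name="Cz")
    if kind == "sphere_meg":
        positions = dirs * 10.0
        names = [f"M{i + 1}" for i in range(n)]
        return SensorLayout(names, positions, "meg", reference_name="none",
                            orientations=dirs)
    raise ValueError(f"unknown layout kind {kind!r}")


def waveform(kind: str, params: dict, time_axis: np.ndarray) -> np.ndarray:
    """Source time courses: gaussian_pulse, sinusoid, chirp, custom.

    ``chirp`` sweeps a linear instantaneous frequency f0 → f1 over the
    epoch: ``amp · sin(2π ∫ f(t) dt)``.
    """
    t = np.asarray(time_axis, dtype=float)
    if kind == "gaussian_pulse":
        c, sd, amp = params["center"], params["sd"], params.get("amp", 1.0)
        return amp * np.exp(-((t - c) ** 2) / (2 * sd**2))
    if kind == "sinusoid":
        f, phase, amp = params["f"], params.get("phase", 0.0), params.get("amp", 1.0)
        return amp * np.sin(2 * np.pi * f * t + phase)
    if kind == "chirp":
        f0, f1, amp = params["f0"], params["f1"], params.get("amp", 1.0)
        T = t[-1] - t[0]
        tau = t - t[0]
        phase = 2 * np.pi * (f0 * tau + (f1 - f0) * tau**2 / (2 * T))
        return amp * np.sin(phase + params.get("phase", 0.0))
    if kind == "custom":
        samples = np.asarray(params["samples"], dtype=float)
        if len(samples) != len(t):
            raise ValueError("custom waveform length must match the time axis")
        return samples
    raise ValueError(f"unknown waveform kind {kind!r}")


@dataclass(frozen=True)
class SimSource:
    """One neural source: where, which direction, what time course."""

    radius_fraction: float  # of the outermost default source shell (8 cm)
    direction: tuple[float, float, float]  # unit position direction
    orientation: tuple[float, float, float]  # unit moment direction
    waveform_kind: str = "gaussian_pulse"
    waveform_params: dict = field(default_factory=lambda: {"center": 0.15, "sd": 0.03})
    amplitude_nAm: float = 20.0
    jitter: float = 0.0  # per-trial amplitude SD as a fraction of amplitude

    def position_cm(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        return d / np.linalg.norm(d) * self.radius_fraction * 8.0

    def moment_direction(self) -> np.ndarray:
        o = np.asarray(self.orientation, dtype=float)
        return o / np.linalg.norm(o)


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes of the four noise classes plus ocular artifacts.

    Amplitudes are in sensor units (µV or fT).  ``ar_coefficient``
    controls the temporal correlation of the shared-topography noise;
    ``brain_noise_dipoles`` random dipoles per trial produce the
    spatially correlated class.
    """

    white_sd: float = 0.0
    ar_sd: float = 0.0
    ar_coefficient: float = 0.95
    sensor_sd: float = 0.0
    brain_noise_sd: float = 0.0
    brain_noise_dipoles: int = 10
    blink_rate_hz: float = 0.0
    blink_amplitude: float = 100.0
    include_saccades: bool = False

    def __post_init__(self) -> None:
        for name in ("white_sd", "ar_sd", "sensor_sd", "brain_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("AR coefficient must lie in (-1, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulated dataset."""

    layout_kind: str = "sphere_eeg"
    n_sensors: int = 32
    sources: tuple[SimSource, ...] = ()
    noise: NoiseSpec = NoiseSpec()
    n_trials: int = 20
    n_subjects: int = 1
    fs: float = 250.0
    t_pre_s: float = -0.2
    t_post_s: float = 0.6
    seed: int = 0
    output: str = "single_trial"  # or "averaged"
    condition_code: int = 1


@dataclass
class GroundTruth:
    """Everything that was drawn while simulating."""

    config: SimConfig
    source_positions_cm: np.ndarray
    source_moments: np.ndarray
    trial_amplitudes: np.ndarray  # (n_trials, n_sources)
    ar_topography: np.ndarray | None
    sensor_noise_scales: np.ndarray | None
    blink_onsets_s: list
    subject_gains: np.ndarray | None = None


_BLINK_DURATION_S = 0.4


def _blink_topography(layout: SensorLayout, head: HeadModel | None) -> np.ndarray:
    """Topography of a blink: two dipoles just above the eyes, pointing
    up-and-forward, producing a frontal-positive potential."""
    r = 0.85 * 8.0
    eyes = np.array(
        [[0.30, 0.90, -0.25], [-0.30, 0.90, -0.25]]
    )
    eyes = eyes / np.linalg.norm(eyes, axis=1, keepdims=True) * r
    mom = np.array([[0.0, 0.35, 0.90], [0.0, 0.35, 0.90]])
    mom = mom / np.linalg.norm(mom, axis=1, keepdims=True)
    topo = forward_dipoles(layout, eyes, mom, head=head).sum(axis=1)
    front = layout.positions[:, 1] > 0
    if topo[front].mean() < 0:
        topo = -topo
    return topo


def simulate(config: SimConfig):
    """Generate an :class:`EpochSet` (or per-subject averages) plus truth.

    Per trial the sensor data are the sum of each source's forward
    projection scaled by a jittered amplitude, the four noise classes
    and any ocular artifacts.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    layout = make_layout(config.layout_kind, config.n_sensors)
    head = HeadModel()
    n_pre = int(round(-config.t_pre_s * config.fs))
    n_post = int(round(config.t_post_s * config.fs))
    n_samp = n_pre + n_post + 1
    t0 = -n_pre / config.fs
    times = t0 + np.arange(n_samp) / config.fs

    src_pos = np.array([s.position_cm() for s in config.sources]).reshape(-1, 3)
    src_mom = np.array([s.moment_direction() for s in config.sources]).reshape(-1, 3)
    if len(config.sources):
        max_r = np.linalg.norm(src_pos, axis=1).max()
        if max_r >= head.shell_radii_cm[0]:
            raise ValueError(
                f"source at {max_r:.1f} cm lies outside the innermost conductor "
                f"boundary ({head.shell_radii_cm[0]} cm)"
            )
        gains = forward_dipoles(layout, src_pos, src_mom, head=head)  # (S, Q)
        courses = np.stack(
            [waveform(s.waveform_kind, s.waveform_params, times) for s in config.sources]
        )  # (Q, T)
    else:
        gains = np.zeros((layout.n_sensors, 0))
        courses = np.zeros((0, n_samp))

    noise = config.noise
    ar_topo = None
    if noise.ar_sd > 0:
        ar_topo = rng.normal(size=layout.n_sensors)
        ar_topo /= np.linalg.norm(ar_topo) / np.sqrt(layout.n_sensors)
    sensor_scales = None
    if noise.sensor_sd > 0:
        sensor_scales = noise.sensor_sd * np.exp(rng.normal(0, 0.5, layout.n_sensors))
    blink_topo = (
        _blink_topography(layout, head) if noise.blink_rate_hz > 0 else None
    )

    def one_dataset(ds_rng: np.random.Generator):
        data = np.zeros((config.n_trials, layout.n_sensors, n_samp))
        amps = np.ones((config.n_trials, len(config.sources)))
        blink_onsets: list = []
        for t in range(config.n_trials):
            for q, s in enumerate(config.sources):
                a = s.amplitude_nAm
                if s.jitter > 0:
                    a = a * (1.0 + s.jitter * ds_rng.normal())
                amps[t, q] = a
                data[t] += np.outer(gains[:, q], a * courses[q])
            if noise.white_sd > 0:
                data[t] += ds_rng.normal(0, noise.white_sd, (layout.n_sensors, n_samp))
            if noise.ar_sd > 0:
                innov = ds_rng.normal(0, 1.0, n_samp)
                series = np.empty(n_samp)
                series[0] = innov[0]
                for i in range(1, n_samp):
                    series[i] = noise.ar_coefficient * series[i - 1] + innov[i]
                series *= noise.ar_sd * np.sqrt(1 - noise.ar_coefficient**2)
                data[t] += np.outer(ar_topo, series)
            if sensor_scales is not None:
                data[t] += sensor_scales[:, None] * ds_rng.normal(
                    0, 1.0, (layout.n_sensors, n_samp)
                )
            if noise.brain_noise_sd > 0:
                nd = noise.brain_noise_dipoles
                dirs = ds_rng.normal(size=(nd, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                radii = 8.0 * ds_rng.uniform(0.3, 0.95, nd) ** (1 / 3)
                moms = ds_rng.normal(size=(nd, 3))
                moms /= np.linalg.norm(moms, axis=1, keepdims=True)
                bg = forward_dipoles(layout, dirs * radii[:, None], moms, head=head)
                bcourse = ds_rng.normal(0, 1.0, (nd, n_samp))
                raw = bg @ bcourse
                raw *= noise.brain_noise_sd / max(raw.std(), 1e-12)
                data[t] += raw
            if blink_topo is not None:
                duration = times[-1] - times[0]
                n_blinks = ds_rng.poisson(noise.blink_rate_hz * duration)
                onsets = ds_rng.uniform(times[0], times[-1] - _BLINK_DURATION_S,
                                        size=n_blinks)
                blink_onsets.append(sorted(onsets.tolist()))
                for onset in onsets:
                    sel = (times >= onset) & (times <= onset + _BLINK_DURATION_S)
                    shape = 0.5 * (
                        1 - np.cos(2 * np.pi * (times[sel] - onset) / _BLINK_DURATION_S)
                    )
                    scale = noise.blink_amplitude / max(np.abs(blink_topo).max(), 1e-12)
                    data[t][:, sel] += np.outer(blink_topo * scale, shape)
            else:
                blink_onsets.append([])
        return data, amps, blink_onsets

    if config.output == "single_trial":
        data, amps, blink_onsets = one_dataset(rng)
        epochs = EpochSet(
            data=data,
            fs=config.fs,
            t0=t0,
            layout=layout,
            conditions=ConditionTable.from_codes(
                [config.condition_code] * config.n_trials
            ),
        )
        truth = GroundTruth(
            config=config,
            source_positions_cm=src_pos,
            source_moments=src_mom,
            trial_amplitudes=amps,
            ar_topography=ar_topo,
            sensor_noise_scales=sensor_scales,
            blink_onsets_s=blink_onsets,
        )
        return epochs, truth

    if config.output == "averaged":
        subject_gains = 1.0 + 0.1 * rng.normal(size=config.n_subjects)
        averages, all_amps, all_blinks = [], [], []
        for s in range(config.n_subjects):
            data, amps, blinks = one_dataset(rng)
            averages.append(
                EvokedAverage(
                    data=subject_gains[s] * data.mean(axis=0),
                    fs=config.fs,
                    t0=t0,
                    layout=layout,
                    condition_code=config.condition_code,
                    n_trials_used=config.n_trials,
                )
            )
            all_amps.append(amps)
            all_blinks.append(blinks)
        truth = GroundTruth(
            config=config,
            source_positions_cm=src_pos,
            source_moments=src_mom,
            trial_amplitudes=np.stack(all_amps),
            ar_topography=ar_topo,
            sensor_noise_scales=sensor_scales,
            blink_onsets_s=all_blinks,
            subject_gains=subject_gains,
        )
        return averages, truth

    raise ValueError(f"unknown output kind {config.output!r}")


def _replace_field(config: SimConfig, dotted: str, value):
    parts = dotted.split(".")
    if len(parts) == 1:
        current = getattr(config, parts[0])
        if not isinstance(current, (int, float)) or isinstance(current, bool):
            raise ValueError(f"config field {dotted!r} is not numeric")
        return replace(config, **{parts[0]: value})
    if parts[0] == "noise":
        current = getattr(config.noise, parts[1])
        if not isinstance(current, (int, float)) or isinstance(current, bool):
            raise ValueError(f"config field {dotted!r} is not numeric")
        return replace(config, noise=replace(config.noise, **{parts[1]: value}))
    if parts[0] == "sources":
        idx = int(parts[1])
        current = getattr(config.sources[idx], parts[2])
        if not isinstance(current, (int, float)) or isinstance(current, bool):
            raise ValueError(f"config field {dotted!r} is not numeric")
        sources = list(config.sources)
        sources[idx] = replace(sources[idx], **{parts[2]: value})
        return replace(config, sources=tuple(sources))
    raise ValueError(f"cannot address config field {dotted!r}")


def vary_across(config: SimConfig, parameter: str, values: Sequence[float]) -> list:
    """Simulate one dataset per parameter value.

    ``parameter`` addresses a numeric config field with dots, e.g.
    ``"noise.white_sd"`` or ``"sources.0.amplitude_nAm"``.  Each
    dataset's seed derives deterministically from the master seed.
    """
    out = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(values))
    for child, v in zip(children, values):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = _replace_field(config, parameter, v)
        cfg = replace(cfg, seed=sub_seed)
        out.append(simulate(cfg))
    return out
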
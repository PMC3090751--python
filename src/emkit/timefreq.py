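"""Morlet wavelet time-frequency analysis.

Each analysis frequency f gets a complex Morlet wavelet
``w(t) = A exp(-t²/(2σ_t²)) exp(i 2π f t)`` with ``σ_t = m/(2π f)``
(m = width in cycles, default 7), truncated at ±3σ_t and normalized to
unit total energy.  Convolving single trials with the family yields
per-trial complex coefficients from which three power estimates follow:

* total   — mean over trials of |coefficient|²;
* evoked  — |coefficient of the trial average|² (phase-locked part);
* induced — total − evoked (non-phase-locked part), floored at 0.

The phase-locking factor is the magnitude of the across-trial mean unit
phasor; 1 means perfect phase alignment, and under random phase its
expectation is √(π/(4 n)).

Samples within 2σ_t of the epoch edges are flagged invalid rather than
silently zero-padded, so downstream statistics can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .containers import EpochSet

__all__ = [
    "WaveletSpec",
    "TFResult",
    "morlet_family",
    "tf_transform",
    "tf_power",
    "phase_locking_factor",
    "tf_baseline",
    "tf_combine",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet family parameters: analysis frequencies, width, rate."""

    frequencies_hz: tuple[float, ...]
    width: float = 7.0
    fs: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if np.any(f <= 0) or (self.fs and np.any(f >= self.fs / 2)):
            raise ValueError("frequencies must lie in (0, fs/2)")
        if self.width < 3:
            raise ValueError("wavelet width below 3 cycles is not supported")
        if self.width < 5:
            warnings.warn("wavelet width below 5 cycles gives poor frequency resolution")

    @staticmethod
    def linspace(fmin: float, fmax: float, n: int, fs: float, width: float = 7.0,
                 spacing: str | None = None) -> "WaveletSpec":
        """Linear or logarithmic frequency grid; defaults to log spacing
        when fmax/fmin > 4 (variable frequency resolution)."""
        if spacing is None:
            spacing = "log" if fmax / fmin > 4 else "linear"
        if spacing == "log":
            freqs = np.geomspace(fmin, fmax, n)
        else:
            freqs = np.linspace(fmin, fmax, n)
        return WaveletSpec(tuple(freqs), width=width, fs=fs)

    def sigma_t(self) -> np.ndarray:
        f = np.asarray(self.frequencies_hz)
        return self.width / (2 * np.pi * f)


@dataclass
class TFResult:
    """Time-frequency result: channels × frequencies × times."""

    power: np.ndarray | None
    freqs: np.ndarray
    times: np.ndarray
    kind: str  # total | evoked | induced | plf
    plf: np.ndarray | None = None
    n_trials: int = 0
    baseline_mode: str | None = None
    valid: np.ndarray | None = None  # (freqs, times) bool, False near edges
    units: str = "uV^2"

    def copy(self) -> "TFResult":
        return TFResult(
            power=None if self.power is None else self.power.copy(),
            freqs=self.freqs.copy(),
            times=self.times.copy(),
            kind=self.kind,
            plf=None if self.plf is None else self.plf.copy(),
            n_trials=self.n_trials,
            baseline_mode=self.baseline_mode,
            valid=None if self.valid is None else self.valid.copy(),
            units=self.units,
        )


def morlet_family(spec: WaveletSpec) -> list[np.ndarray]:
    """Complex Morlet wavelets, unit energy, truncated at ±3σ_t."""
    if spec.fs <= 0:
        raise ValueError("spec.fs must be set")
    dt = 1.0 / spec.fs
    out = []
    for f, st in zip(spec.frequencies_hz, spec.sigma_t()):
        half = int(np.ceil(3 * st * spec.fs))
        t = np.arange(-half, half + 1) * dt
        w = np.exp(-(t**2) / (2 * st**2)) * np.exp(2j * np.pi * f * t)
        energy = np.sum(np.abs(w) ** 2) * dt
        out.append(w / np.sqrt(energy))
    return out


def _check_lengths(wavelets, spec, n_samples):
    for f, w in zip(spec.frequencies_hz, wavelets):
        if len(w) > n_samples:
            raise ValueError(
                f"wavelet at {f:g} Hz ({len(w)} samples) is longer than the "
                f"epoch ({n_samples} samples)"
            )


def tf_transform(data: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Complex wavelet coefficients of (..., n_samples) data.

    Returns an array of shape ``(..., n_freqs, n_samples)``.
    """
    data = np.asarray(data, dtype=float)
    wavelets = morlet_family(spec)
    _check_lengths(wavelets, spec, data.shape[-1])
    flat = data.reshape(-1, data.shape[-1])
    coeffs = np.empty((flat.shape[0], len(wavelets), flat.shape[1]), dtype=complex)
    for j, w in enumerate(wavelets):
        for i in range(flat.shape[0]):
            coeffs[i, j] = scipy.signal.fftconvolve(flat[i], w, mode="same")
    return coeffs.reshape(data.shape[:-1] + coeffs.shape[1:])


def _valid_mask(spec: WaveletSpec, times: np.ndarray) -> np.ndarray:
    sig = spec.sigma_t()
    lo = times[0] + 2 * sig[:, None]
    hi = times[-1] - 2 * sig[:, None]
    return (times[None, :] >= lo) & (times[None, :] <= hi)


def tf_power(epochs: EpochSet, spec: WaveletSpec, kind: str = "total") -> TFResult:
    """Wavelet power: total, evoked or induced (see module docstring)."""
    if kind not in ("total", "evoked", "induced"):
        raise ValueError(f"unknown power kind {kind!r}")
    if kind in ("total", "induced") and epochs.n_trials < 2:
        raise ValueError(f"{kind} power needs single-trial data (≥2 trials)")
    times = epochs.times
    units = "uV^2" if epochs.layout.modality == "eeg" else "fT^2"
    if kind == "evoked":
        avg = epochs.data.mean(axis=0)
        power = np.abs(tf_transform(avg, spec)) ** 2
    else:
        coeffs = tf_transform(epochs.data, spec)
        total = (np.abs(coeffs) ** 2).mean(axis=0)
        if kind == "total":
            power = total
        else:
            avg = epochs.data.mean(axis=0)
            evoked = np.abs(tf_transform(avg, spec)) ** 2
            power = np.clip(total - evoked, 0.0, None)
    return TFResult(
        power=power,
        freqs=np.asarray(spec.frequencies_hz),
        times=times,
        kind=kind,
        n_trials=epochs.n_trials,
        valid=_valid_mask(spec, times),
        units=units,
    )


def phase_locking_factor(epochs: EpochSet, spec: WaveletSpec) -> TFResult:
    """Across-trial phase consistency in [0, 1], independent of amplitude."""
    if epochs.n_trials < 2:
        raise ValueError("the phase-locking factor needs at least 2 trials")
    coeffs = tf_transform(epochs.data, spec)
    mag = np.abs(coeffs)
    phasors = coeffs / np.where(mag > 0, mag, 1.0)
    plf = np.abs(phasors.mean(axis=0))
    return TFResult(
        power=None,
        freqs=np.asarray(spec.frequencies_hz),
        times=epochs.times,
        kind="plf",
        plf=plf,
        n_trials=epochs.n_trials,
        valid=_valid_mask(spec, epochs.times),
        units="",
    )


def tf_baseline(
    tf: TFResult, window_s: tuple[float, float], mode: str = "percent"
) -> TFResult:
    """Normalize power to a pre-stimulus baseline window.

    ``percent`` = 100 (P − μ)/μ, ``db`` = 10 log₁₀(P/μ), ``zscore`` =
    (P − μ)/σ, with μ and σ over the baseline samples per channel and
    frequency.
    """
    if tf.power is None:
        raise ValueError("result carries no power to normalize")
    if mode not in ("percent", "db", "zscore"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    lo, hi = window_s
    if lo >= hi or lo < tf.times[0] or hi > 0:
        raise ValueError("baseline window must precede 0 and lie inside the epoch")
    sel = (tf.times >= lo) & (tf.times <= hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    mu = tf.power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(mu == 0):
        raise ValueError("zero baseline power; cannot normalize")
    out = tf.copy()
    if mode == "percent":
        out.power = 100.0 * (tf.power - mu) / mu
        out.units = "%"
    elif mode == "db":
        out.power = 10.0 * np.log10(tf.power / mu)
        out.units = "dB"
    else:
        sd = tf.power[..., sel].std(axis=-1, ddof=1, keepdims=True)
        out.power = (tf.power - mu) / np.where(sd > 0, sd, np.inf)
        out.units = "z"
    out.baseline_mode = mode
    return out


def tf_combine(results: list[TFResult], op: str = "average") -> TFResult:
    """Elementwise combination of compatible results.

    ``average`` weights by n_trials, ``grand_average`` weights each
    result (subject) equally, ``difference`` takes exactly two results.
    """
    if not results:
        raise ValueError("no results to combine")
    first = results[0]
    for r in results[1:]:
        if (
            r.power is None
            or first.power is None
            or r.power.shape != first.power.shape
            or not np.allclose(r.freqs, first.freqs)
            or not np.allclose(r.times, first.times)
        ):
            raise ValueError("results must share axes and carry power")
    if op == "difference":
        if len(results) != 2:
            raise ValueError("difference takes exactly 2 results")
        out = first.copy()
        out.power = first.power - results[1].power
        out.kind = f"difference({first.kind})"
        return out
    if op == "average":
        weights = np.array([r.n_trials for r in results], dtype=float)
        if weights.sum() == 0:
            raise ValueError("cannot trial-weight results with n_trials 0")
    elif op == "grand_average":
        weights = np.ones(len(results))
    else:
        raise ValueError(f"unknown combination {op!r}")
    weights = weights / weights.sum()
    out = first.copy()
    out.power = sum(w * r.power for w, r in zip(weights, results))
    out.n_trials = int(sum(r.n_trials for r in results))
    return out
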
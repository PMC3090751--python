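"""Filtering, epoching, condition recoding, re-referencing, baseline
correction and ocular regression correction.

Filtering operates on continuous data only; epoching afterwards avoids
the edge artifacts that filtering short segments would produce and keeps
very low high-pass cutoffs usable.  Zero-phase filtering applies the
filter forward and backward (squared magnitude response, zero net
phase); one-pass FIR filtering compensates the linear-phase group delay
so event-related latencies are preserved either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.signal

from .containers import ConditionTable, ContinuousRecording, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "RealizedFilter",
    "EogCorrection",
    "design_filter",
    "filter_continuous",
    "extract_epochs",
    "recode_conditions",
    "rereference",
    "baseline_correct",
    "gratton_eog_correct",
]


@dataclass(frozen=True)
class FilterSpec:
    """Filter request: family, band edges and design parameters.

    ``family``: ``butterworth`` (IIR, uses ``order``), ``kaiser`` or
    ``firls`` (FIR, use ``length`` taps; ``kaiser`` takes a window
    ``beta``, ``firls`` a transition band width in Hz).
    """

    family: str
    kind: str  # lowpass | highpass | bandpass
    cutoffs_hz: float | tuple[float, float]
    order: int = 4
    length: int = 101
    beta: float = 8.6
    transition_hz: float | None = None
    zero_phase: bool = True

    def cutoffs(self) -> tuple[float, ...]:
        c = self.cutoffs_hz
        return tuple(c) if isinstance(c, (tuple, list)) else (float(c),)

    def validate(self, fs: float) -> None:
        if self.family not in ("butterworth", "kaiser", "firls"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        cuts = self.cutoffs()
        if any(not 0 < c < fs / 2 for c in cuts):
            raise ValueError(f"cutoffs {cuts} must lie in (0, fs/2)")
        if self.kind == "bandpass":
            if len(cuts) != 2 or cuts[0] >= cuts[1]:
                raise ValueError("bandpass needs cutoffs (low, high) with low < high")
        elif len(cuts) != 1:
            raise ValueError(f"{self.kind} takes a single cutoff")


@dataclass
class RealizedFilter:
    """Designed filter coefficients plus a transfer-function evaluator."""

    spec: FilterSpec
    fs: float
    sos: np.ndarray | None = None  # IIR second-order sections
    taps: np.ndarray | None = None  # FIR impulse response

    @property
    def is_fir(self) -> bool:
        return self.taps is not None

    def response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex one-pass frequency response at the given frequencies."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        w = 2 * np.pi * freqs_hz / self.fs
        if self.is_fir:
            _, h = scipy.signal.freqz(self.taps, worN=w)
        else:
            _, h = scipy.signal.sosfreqz(self.sos, worN=w)
        return h

    def magnitude(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Effective magnitude response (squared for zero-phase filtering)."""
        mag = np.abs(self.response(freqs_hz))
        return mag**2 if self.spec.zero_phase else mag


def design_filter(spec: FilterSpec, fs: float) -> RealizedFilter:
    """Design the requested filter for sampling rate ``fs``.

    Raises a ``ValueError`` for invalid band edges and for an unstable
    IIR design (poles on or outside the unit circle).
    """
    spec.validate(fs)
    cuts = spec.cutoffs()
    btype = {"lowpass": "lowpass", "highpass": "highpass", "bandpass": "bandpass"}[
        spec.kind
    ]
    if spec.family == "butterworth":
        sos = scipy.signal.butter(
            spec.order, cuts if len(cuts) > 1 else cuts[0], btype=btype, fs=fs,
            output="sos",
        )
        _, poles, _ = scipy.signal.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable IIR design: pole magnitude {np.abs(poles).max():.6f} >= 1"
            )
        return RealizedFilter(spec=spec, fs=fs, sos=sos)
    length = spec.length + (spec.length % 2 == 0)  # odd length, linear phase type I
    if spec.family == "kaiser":
        taps = scipy.signal.firwin(
            length,
            cuts if len(cuts) > 1 else cuts[0],
            window=("kaiser", spec.beta),
            pass_zero={"lowpass": True, "highpass": False, "bandpass": False}[
                spec.kind
            ],
            fs=fs,
        )
    else:  # firls
        tw = spec.transition_hz or max(0.5, 0.2 * cuts[0])
        nyq = fs / 2
        if spec.kind == "lowpass":
            bands = [0, cuts[0], min(cuts[0] + tw, nyq * 0.999), nyq]
            desired = [1, 1, 0, 0]
        elif spec.kind == "highpass":
            bands = [0, max(cuts[0] - tw, 1e-6), cuts[0], nyq]
            desired = [0, 0, 1, 1]
        else:
            lo, hi = cuts
            bands = [
                0,
                max(lo - tw, 1e-6),
                lo,
                hi,
                min(hi + tw, nyq * 0.999),
                nyq,
            ]
            desired = [0, 0, 1, 1, 0, 0]
        taps = scipy.signal.firls(length, bands, desired, fs=fs)
    return RealizedFilter(spec=spec, fs=fs, taps=taps)


def filter_continuous(
    recording: ContinuousRecording, spec: FilterSpec | RealizedFilter
) -> ContinuousRecording:
    """Filter every channel of a continuous recording over its full length.

    Epoched input is rejected: the pipeline contract is that filtering
    always precedes epoching.
    """
    if isinstance(recording, EpochSet):
        raise TypeError(
            "filter_continuous operates on continuous data; filter before epoching"
        )
    filt = (
        spec if isinstance(spec, RealizedFilter) else design_filter(spec, recording.fs)
    )
    x = recording.data
    if filt.is_fir:
        if filt.spec.zero_phase:
            y = scipy.signal.filtfilt(filt.taps, [1.0], x, axis=1)
        else:
            # group-delay compensated one-pass linear-phase FIR
            full = scipy.signal.lfilter(filt.taps, [1.0], np.pad(
                x, ((0, 0), (0, len(filt.taps) // 2)), mode="edge"), axis=1)
            y = full[:, len(filt.taps) // 2 :]
    else:
        if filt.spec.zero_phase:
            y = scipy.signal.sosfiltfilt(filt.sos, x, axis=1)
        else:
            y = scipy.signal.sosfilt(filt.sos, x, axis=1)
    return replace(recording, data=y)


def extract_epochs(
    recording: ContinuousRecording,
    triggers,
    codes_of_interest: Sequence[int],
    t_pre_s: float,
    t_post_s: float,
) -> EpochSet:
    """Cut trigger-locked epochs out of a continuous recording.

    The epoch window is ``[t_pre, t_post]`` seconds around each trigger
    (``t_pre <= 0``); trials whose window does not fit in the recording
    are dropped with a logged warning.
    """
    if not (t_pre_s <= 0 <= t_post_s):
        raise ValueError("need t_pre_s <= 0 <= t_post_s")
    selected = triggers.select(codes_of_interest)
    if len(selected) == 0:
        raise ValueError(
            f"no trigger events with codes {list(codes_of_interest)} found"
        )
    n_pre = int(np.floor(-t_pre_s * recording.fs))
    n_post = int(np.floor(t_post_s * recording.fs))
    n_len = n_pre + n_post + 1
    trials, codes = [], []
    dropped = 0
    for sample, code in selected.events:
        start = sample - n_pre
        stop = sample + n_post + 1
        if start < 0 or stop > recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.data[:, start:stop])
        codes.append(code)
    if dropped:
        logger.warning("dropped %d epoch(s) exceeding the recording bounds", dropped)
    if not trials:
        raise ValueError("all epochs fell outside the recording")
    return EpochSet(
        data=np.stack(trials),
        fs=recording.fs,
        t0=-n_pre / recording.fs,
        layout=recording.layout,
        conditions=ConditionTable.from_codes(codes),
    )


def recode_conditions(table: ConditionTable, scheme) -> ConditionTable:
    """Recode a condition table.

    ``scheme`` is one of:

    * ``{"map": {old: new, ...}}`` — relabel codes;
    * ``{"balance": True}`` — equalize trial counts per code by marking
      surplus trials ``include=False``, keeping the chronologically
      first k per code (k = smallest per-code count among included
      trials);
    * ``{"odd_even": True}`` — split each code's successive occurrences
      alternately into ``code*10+1`` and ``code*10+2``.
    """
    out = table.copy()
    if "map" in scheme:
        mapping = scheme["map"]
        unknown = sorted(set(out.code.tolist()) - set(mapping))
        if unknown:
            raise ValueError(f"map does not cover codes {unknown}")
        out.code = np.array([mapping[c] for c in out.code])
        return out
    if scheme.get("balance"):
        order = np.argsort(out.trial_index)
        counts = {}
        for idx in order:
            if out.include[idx]:
                counts[out.code[idx]] = counts.get(out.code[idx], 0) + 1
        if not counts:
            return out
        k = min(counts.values())
        seen: dict[int, int] = {}
        for idx in order:
            if not out.include[idx]:
                continue
            c = out.code[idx]
            seen[c] = seen.get(c, 0) + 1
            if seen[c] > k:
                out.include[idx] = False
        return out
    if scheme.get("odd_even"):
        order = np.argsort(out.trial_index)
        seen = {}
        new_codes = out.code.copy()
        for idx in order:
            c = out.code[idx]
            seen[c] = seen.get(c, 0) + 1
            new_codes[idx] = c * 10 + (1 if seen[c] % 2 == 1 else 2)
        out.code = new_codes
        return out
    raise ValueError(f"unknown recoding scheme {scheme!r}")


def rereference(obj, target: str):
    """Re-reference EEG data to the instantaneous channel average or to
    a named sensor.  MEG data have no reference and are rejected."""
    if obj.layout.modality != "eeg":
        raise ValueError("re-referencing applies to EEG data only")
    data = obj.data
    axis = data.ndim - 2  # channel axis for both epochs and continuous
    if target == "average":
        ref = data.mean(axis=axis, keepdims=True)
    else:
        idx = obj.layout.index(target)
        ref = np.take(data, [idx], axis=axis)
    new_layout = replace(
        obj.layout, reference_name="average" if target == "average" else target
    )
    return replace(obj, data=data - ref, layout=new_layout)


def baseline_correct(epochs: EpochSet, window_s: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over a time window."""
    times = epochs.times
    sel = (times >= window_s[0]) & (times <= window_s[1])
    if not sel.any():
        raise ValueError(f"baseline window {window_s} contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, sel].mean(axis=2, keepdims=True)
    return out


@dataclass
class EogCorrection:
    """Ocular propagation coefficients (EOG channels × EEG channels)."""

    propagation: np.ndarray
    eog_channel_names: list[str]
    eeg_channel_names: list[str]


def gratton_eog_correct(
    epochs: EpochSet, eog_channel_names: Sequence[str]
) -> tuple[EpochSet, EogCorrection]:
    """Regression-based ocular artifact correction.

    The event-related signal is first removed by subtracting each
    trial's condition average; the propagation of ocular activity into
    each EEG channel is then estimated by regressing the EEG residuals
    on the EOG residuals, pooled over trials and time.  The scaled raw
    EOG is finally subtracted from the raw EEG.  By construction the
    coefficients are insensitive to any event-locked component.
    """
    eog_idx = [epochs.layout.index(n) for n in eog_channel_names]
    if not eog_idx:
        raise ValueError("at least one EOG channel is required")
    if epochs.n_trials < 2:
        raise ValueError("regression correction needs at least 2 trials")
    eeg_idx = [i for i in range(epochs.n_channels) if i not in eog_idx]

    data = epochs.data
    resid = data.copy()
    for code in np.unique(epochs.conditions.code):
        rows = np.nonzero(epochs.conditions.code == code)[0]
        resid[rows] -= data[rows].mean(axis=0, keepdims=True)

    E = resid[:, eog_idx, :].transpose(1, 0, 2).reshape(len(eog_idx), -1)
    G = resid[:, eeg_idx, :].transpose(1, 0, 2).reshape(len(eeg_idx), -1)
    if np.all(data[:, eog_idx, :] == 0):
        # no ocular signal at all: nothing to regress out
        coef = np.zeros((len(eog_idx), len(eeg_idx)))
        return epochs.copy(), EogCorrection(
            coef,
            [epochs.layout.names[i] for i in eog_idx],
            [epochs.layout.names[i] for i in eeg_idx],
        )
    cov = E @ E.T
    eog_scale = np.abs(data[:, eog_idx, :]).max()
    degenerate = np.abs(E).max() < 1e-10 * eog_scale  # constant EOG: zero residual
    if degenerate or np.linalg.cond(cov) > 1e10:
        raise ValueError(
            "singular EOG covariance (constant or collinear EOG channels)"
        )
    coef = np.linalg.solve(cov, E @ G.T)  # (n_eog, n_eeg)

    out = epochs.copy()
    eog_raw = data[:, eog_idx, :]
    out.data[:, eeg_idx, :] -= np.einsum("ge,tgs->tes", coef, eog_raw)
    return out, EogCorrection(
        coef,
        [epochs.layout.names[i] for i in eog_idx],
        [epochs.layout.names[i] for i in eeg_idx],
    )
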
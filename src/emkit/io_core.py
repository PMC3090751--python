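"""File I/O: EDF/BDF continuous data, trigger/condition/layout text
tables, and the internal epoch container.

The EDF (16-bit) and BDF (Biosemi, 24-bit) readers and writers follow
the published format layouts directly so that digital values survive a
write→read round trip bit-exactly.  Physical scaling is the affine
``digital_min/max ↔ physical_min/max`` map from each signal header; the
scale actually used for quantization is re-parsed from the serialized
ASCII header fields, so a round trip is exact to one quantization step.

The internal epoch container is a directory holding a YAML header
(dimensions, rates, labels, creation log), a raw little-endian float32
payload ordered trial-major then channel-major, the condition table and
the sensor layout as editable text.  The text files are authoritative:
editing them changes what is read back.
"""

from __future__ import annotations

import datetime
import os
from pathlib import Path

import numpy as np
import yaml

from .containers import (
    ConditionTable,
    ContinuousRecording,
    EpochSet,
    SensorLayout,
    TriggerTable,
)

__all__ = [
    "read_continuous",
    "write_continuous",
    "extract_trigger_events",
    "read_trigger_text",
    "write_trigger_text",
    "read_condition_text",
    "write_condition_text",
    "read_layout_text",
    "write_layout_text",
    "write_epoch_container",
    "read_epoch_container",
    "FormatError",
]

_STATUS_LABELS = {"status", "trigger", "sti 014"}


class FormatError(ValueError):
    """Malformed EDF/BDF file; carries the byte offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)
        self.offset = offset


# ---------------------------------------------------------------------------
# EDF / BDF


def _ascii(field: bytes) -> str:
    return field.decode("ascii", errors="replace").strip()


def _fixed(text: str, width: int) -> bytes:
    s = text[:width].ljust(width)
    return s.encode("ascii")


def _num_field(value: float, width: int = 8) -> str:
    """Format a number into an EDF ASCII field of fixed width."""
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return fmt
    return f"{value:.1e}"[:width]


def read_continuous(
    path: str | os.PathLike,
    fmt: str | None = None,
    layout: SensorLayout | None = None,
) -> ContinuousRecording:
    """Read an EDF (16-bit) or BDF (Biosemi 24-bit) continuous recording.

    The status/trigger channel (label ``Status``, ``Trigger`` or
    ``STI 014``) is separated from the data channels and returned as an
    integer sequence.  BDF EEG data are re-referenced to Cz as required
    for Biosemi recordings; a BDF file without a Cz channel is an error.

    Parameters
    ----------
    path
        File to read.
    fmt
        ``"edf"`` or ``"bdf"``; inferred from the header when omitted.
    layout
        Optional sensor layout; channels are reordered to match it and
        channels absent from it are dropped.  Without a layout, a
        position-less placeholder layout is built from the file labels.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError("file shorter than the 256-byte header", len(raw))
    magic = raw[:8]
    if magic[0:1] == b"\xff" and magic[1:8] == b"BIOSEMI":
        detected = "bdf"
    elif _ascii(magic) == "0":
        detected = "edf"
    else:
        raise FormatError(f"unrecognized version field {magic!r}", 0)
    if fmt is not None and fmt.lower() != detected:
        raise FormatError(f"requested {fmt} but file header says {detected}", 0)
    fmt = detected
    sample_bytes = 3 if fmt == "bdf" else 2

    try:
        n_records = int(_ascii(raw[236:244]))
        record_dur = float(_ascii(raw[244:252]))
        n_signals = int(_ascii(raw[252:256]))
    except ValueError as exc:
        raise FormatError(f"malformed numeric header field: {exc}", 236) from None
    header_bytes = 256 + 256 * n_signals
    if len(raw) < header_bytes:
        raise FormatError("file truncated inside the signal headers", len(raw))

    labels, phys_dim, phys_min, phys_max, dig_min, dig_max, ns = _parse_signal_headers(
        raw, n_signals
    )

    payload = raw[header_bytes:]
    rec_len = sum(ns) * sample_bytes
    if n_records < 0:  # unknown length: infer
        n_records = len(payload) // rec_len
    if len(payload) < n_records * rec_len:
        raise FormatError(
            f"payload holds {len(payload)} bytes, expected {n_records * rec_len}",
            header_bytes,
        )

    digital = [np.empty(n_records * n, dtype=np.int32) for n in ns]
    pos = 0
    for r in range(n_records):
        for i, n in enumerate(ns):
            chunk = payload[pos : pos + n * sample_bytes]
            pos += n * sample_bytes
            if sample_bytes == 2:
                vals = np.frombuffer(chunk, dtype="<i2").astype(np.int32)
            else:
                b = np.frombuffer(chunk, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
                vals = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
                vals = (vals ^ 0x800000) - 0x800000
            digital[i][r * n : (r + 1) * n] = vals

    if len(set(ns)) > 1:
        raise FormatError("channels with differing sampling rates are not supported")
    fs = ns[0] / record_dur

    status = None
    keep: list[int] = []
    for i, lab in enumerate(labels):
        if lab.strip().lower() in _STATUS_LABELS:
            status = digital[i].astype(np.int64)
            if fmt == "bdf":
                status = status & 0xFFFF  # trigger word lives in the low bits
        else:
            keep.append(i)

    data = np.empty((len(keep), n_records * ns[0]))
    names = []
    for row, i in enumerate(keep):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[row] = (digital[i] - dig_min[i]) * gain + phys_min[i]
        names.append(labels[i])

    if fmt == "bdf":
        cz = [i for i, n in enumerate(names) if n.strip().lower() == "cz"]
        if not cz:
            raise FormatError(
                "BDF requires re-referencing to Cz but no Cz channel found; "
                f"available labels: {names}"
            )
        data = data - data[cz[0]]

    if layout is not None:
        order = []
        for name in layout.names:
            if name not in names:
                raise FormatError(f"layout channel {name!r} not found in file")
            order.append(names.index(name))
        data = data[order]
    else:
        layout = SensorLayout(
            names=names,
            positions=np.zeros((len(names), 3)),
            modality="eeg",
            reference_name="Cz" if fmt == "bdf" else "none",
        )
    return ContinuousRecording(data=data, fs=fs, layout=layout, status=status)


def _sig_block(raw: bytes, n: int, start: int, width: int) -> list[str]:
    base = 256 + start
    return [_ascii(raw[base + i * width : base + (i + 1) * width]) for i in range(n)]


def _parse_signal_headers(raw: bytes, n: int):
    offsets = [0, 16, 96, 104, 112, 120, 128, 136, 216, 224]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    fields = []
    for off, w in zip(offsets, widths):
        fields.append(_sig_block(raw, n, off * n, w))
    labels, _trans, phys_dim, pmin_s, pmax_s, dmin_s, dmax_s, _filt, ns_s, _res = fields
    try:
        phys_min = [float(v) for v in pmin_s]
        phys_max = [float(v) for v in pmax_s]
        dig_min = [int(float(v)) for v in dmin_s]
        dig_max = [int(float(v)) for v in dmax_s]
        ns = [int(v) for v in ns_s]
    except ValueError as exc:
        raise FormatError(f"malformed signal header field: {exc}", 256) from None
    for i in range(n):
        if dig_max[i] == dig_min[i]:
            raise FormatError(f"signal {labels[i]!r} has an empty digital range", 256)
    return labels, phys_dim, phys_min, phys_max, dig_min, dig_max, ns


def write_continuous(
    recording: ContinuousRecording,
    path: str | os.PathLike,
    fmt: str = "edf",
    reference_to_restore: str | None = None,
) -> None:
    """Write a recording as EDF or BDF.

    Each channel's physical range is spanned by its actual data (with a
    small margin); the status sequence, when present, is written as an
    additional ``Status`` channel with an identity digital↔physical map.
    Uses 1-second data records when the sample count allows, otherwise a
    single record covering the whole file.
    """
    fmt = fmt.lower()
    if fmt not in ("edf", "bdf"):
        raise ValueError("format must be 'edf' or 'bdf'")
    data = recording.data
    n_samples = recording.n_samples
    fs = recording.fs
    if fs == int(fs) and n_samples % int(fs) == 0 and n_samples >= int(fs):
        ns_rec = int(fs)
        n_records = n_samples // ns_rec
        rec_dur = 1.0
    else:
        ns_rec = n_samples
        n_records = 1
        rec_dur = n_samples / fs

    dig_lim = 8388607 if fmt == "bdf" else 32767
    channels = [(name, data[i], "uV") for i, name in enumerate(recording.layout.names)]
    if recording.status is not None:
        channels.append(("Status", recording.status.astype(float), ""))

    sig_headers = []
    digital_tracks = []
    for name, x, dim in channels:
        if name == "Status":
            pmin, pmax = -dig_lim - 1.0, float(dig_lim)
            dmin, dmax = -dig_lim - 1, dig_lim
            dig = np.clip(np.round(x), dmin, dmax).astype(np.int64)
        else:
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                hi = lo + 1.0
            margin = 0.01 * (hi - lo)
            pmin_s = _num_field(lo - margin)
            pmax_s = _num_field(hi + margin)
            pmin, pmax = float(pmin_s), float(pmax_s)
            if pmax <= pmin:
                pmax = pmin + 1.0
            dmin, dmax = -dig_lim - 1, dig_lim
            gain = (pmax - pmin) / (dmax - dmin)
            dig = np.clip(np.round((x - pmin) / gain) + dmin, dmin, dmax).astype(
                np.int64
            )
        sig_headers.append((name, dim, pmin, pmax, dmin, dmax))
        digital_tracks.append(dig)

    n_signals = len(channels)
    header = bytearray()
    if fmt == "bdf":
        header += b"\xff" + _fixed("BIOSEMI", 7)
    else:
        header += _fixed("0", 8)
    header += _fixed("", 80)  # patient
    header += _fixed("", 80)  # recording
    now = datetime.datetime(2000, 1, 1)
    header += _fixed(now.strftime("%d.%m.%y"), 8)
    header += _fixed(now.strftime("%H.%M.%S"), 8)
    header += _fixed(str(256 * (n_signals + 1)), 8)
    header += _fixed("24BIT" if fmt == "bdf" else "", 44)
    header += _fixed(str(n_records), 8)
    header += _fixed(_num_field(rec_dur), 8)
    header += _fixed(str(n_signals), 4)

    for (name, dim, *_rest) in sig_headers:
        header += _fixed(name, 16)
    for _ in sig_headers:
        header += _fixed("", 80)
    for (name, dim, *_rest) in sig_headers:
        header += _fixed(dim, 8)
    for (_n, _d, pmin, pmax, dmin, dmax) in sig_headers:
        header += _fixed(_num_field(pmin), 8)
    for (_n, _d, pmin, pmax, dmin, dmax) in sig_headers:
        header += _fixed(_num_field(pmax), 8)
    for (_n, _d, pmin, pmax, dmin, dmax) in sig_headers:
        header += _fixed(str(dmin), 8)
    for (_n, _d, pmin, pmax, dmin, dmax) in sig_headers:
        header += _fixed(str(dmax), 8)
    for _ in sig_headers:
        header += _fixed("", 80)
    for _ in sig_headers:
        header += _fixed(str(ns_rec), 8)
    for _ in sig_headers:
        header += _fixed("", 32)

    body = bytearray()
    for r in range(n_records):
        for dig in digital_tracks:
            chunk = dig[r * ns_rec : (r + 1) * ns_rec]
            if fmt == "edf":
                body += chunk.astype("<i2").tobytes()
            else:
                u = (chunk & 0xFFFFFF).astype(np.uint32)
                b = np.empty((len(u), 3), dtype=np.uint8)
                b[:, 0] = u & 0xFF
                b[:, 1] = (u >> 8) & 0xFF
                b[:, 2] = (u >> 16) & 0xFF
                body += b.tobytes()
    Path(path).write_bytes(bytes(header) + bytes(body))


# ---------------------------------------------------------------------------
# Trigger extraction and text tables


def extract_trigger_events(recording: ContinuousRecording) -> TriggerTable:
    """Events at every status change to a new nonzero value.

    A change to 0 ends an event without emitting one (0 is the rest
    state); a nonzero value at the first sample counts as a change from
    0 and emits an event.
    """
    if recording.status is None:
        raise ValueError("recording has no status sequence")
    status = np.asarray(recording.status, dtype=np.int64)
    if len(status) == 0:
        return TriggerTable([])
    prev = np.concatenate([[0], status[:-1]])
    onsets = np.nonzero((status != prev) & (status != 0))[0]
    return TriggerTable([(int(i), int(status[i])) for i in onsets])


def write_trigger_text(table: TriggerTable, path: str | os.PathLike) -> None:
    lines = ["# sample code"]
    lines += [f"{s} {c}" for s, c in table.events]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trigger_text(path: str | os.PathLike) -> TriggerTable:
    events = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        s, c = line.split()
        events.append((int(s), int(c)))
    return TriggerTable(events)


def write_condition_text(table: ConditionTable, path: str | os.PathLike) -> None:
    lines = ["# trial code include"]
    for t, c, i in zip(table.trial_index, table.code, table.include):
        lines.append(f"{t} {c} {int(i)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_condition_text(path: str | os.PathLike) -> ConditionTable:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        t, c, i = line.split()
        rows.append((int(t), int(c), bool(int(i))))
    rows.sort()
    return ConditionTable(
        np.array([r[0] for r in rows]),
        np.array([r[1] for r in rows]),
        np.array([r[2] for r in rows]),
    )


def write_layout_text(layout: SensorLayout, path: str | os.PathLike) -> None:
    lines = [
        "# name x y z [ox oy oz] (cm, head-centered)",
        f"# modality {layout.modality} reference {layout.reference_name}",
    ]
    for i, name in enumerate(layout.names):
        parts = [name] + [f"{v:.6g}" for v in layout.positions[i]]
        if layout.orientations is not None:
            parts += [f"{v:.6g}" for v in layout.orientations[i]]
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout_text(path: str | os.PathLike) -> SensorLayout:
    names, pos, ori = [], [], []
    modality, reference = "eeg", "none"
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("# modality"):
            parts = stripped.split()
            modality, reference = parts[2], parts[4]
            continue
        stripped = stripped.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        names.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
        if len(parts) >= 7:
            ori.append([float(v) for v in parts[4:7]])
    return SensorLayout(
        names=names,
        positions=np.array(pos),
        modality=modality,
        reference_name=reference,
        orientations=np.array(ori) if ori else None,
    )


# ---------------------------------------------------------------------------
# Internal epoch container


def write_epoch_container(epochs: EpochSet, path: str | os.PathLike) -> None:
    """Write an EpochSet as a container directory.

    Layout: ``header.yaml`` (dimensions, fs, t0, labels, units, creation
    log), ``data.f32`` (raw little-endian float32, trials × channels ×
    samples in C order), ``conditions.txt`` and ``layout.txt``.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot write an epoch container with zero trials")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    header = {
        "kind": "epochs",
        "n_trials": int(epochs.n_trials),
        "n_channels": int(epochs.n_channels),
        "n_samples": int(epochs.n_samples),
        "fs": float(epochs.fs),
        "t0": float(epochs.t0),
        "units": "uV" if epochs.layout.modality == "eeg" else "fT",
        "payload": "data.f32 little-endian float32 C-order",
        "created_by": "emkit",
    }
    (root / "header.yaml").write_text(yaml.safe_dump(header, sort_keys=False))
    epochs.data.astype("<f4").tofile(root / "data.f32")
    write_condition_text(epochs.conditions, root / "conditions.txt")
    write_layout_text(epochs.layout, root / "layout.txt")


def read_epoch_container(path: str | os.PathLike) -> EpochSet:
    root = Path(path)
    header = yaml.safe_load((root / "header.yaml").read_text())
    shape = (header["n_trials"], header["n_channels"], header["n_samples"])
    payload = np.fromfile(root / "data.f32", dtype="<f4")
    if payload.size != int(np.prod(shape)):
        raise ValueError(
            f"container integrity error: payload has {payload.size} values, "
            f"header promises {np.prod(shape)}"
        )
    layout = read_layout_text(root / "layout.txt")
    conditions = read_condition_text(root / "conditions.txt")
    return EpochSet(
        data=payload.reshape(shape).astype(float),
        fs=header["fs"],
        t0=header["t0"],
        layout=layout,
        conditions=conditions,
    )
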
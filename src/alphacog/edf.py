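"""Minimal EDF/EDF+ reader and writer for whole-second EEG recordings.

The interchange format of the pipeline is European Data Format: 16-bit
integers with per-signal physical/digital scaling, one-second data
records. Phase annotations are written both as an EDF+ annotation signal
(time-stamped annotation lists, TALs) and as a JSON sidecar
``<name>.phases.json`` with the same schema, so plain-EDF consumers keep
the phase timing. On read, EDF+ annotations win; the sidecar is the
fallback.

Only the features the pipeline needs are implemented: one common sampling
rate across EEG signals, microvolt (or mV/V, converted) physical units,
and whole-second record layout. Anything else raises
:class:`~alphacog.errors.UnsupportedFormatError`.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from pathlib import Path

import numpy as np

from .errors import FormatError, UnsupportedFormatError, ValidationError
from .phases import Condition, Phase, PhaseAnnotation
from .recording import Recording

_ANNOT_LABEL = "EDF Annotations"
_DIG_MAX = 32767
_DIG_MIN = -32767


def _field(text: str, width: int) -> bytes:
    """ASCII-encode ``text`` left-justified into ``width`` bytes."""
    raw = text.encode("ascii", errors="replace")
    if len(raw) > width:
        raise ValidationError(f"header field too long: {text!r} > {width} bytes")
    return raw.ljust(width)


def _num_field(value, width: int) -> bytes:
    text = f"{value:.{width}g}"[:width] if isinstance(value, float) else str(value)
    return _field(text, width)


def _phys_text(value: float, width: int) -> str:
    """Decimal representation of ``value`` within ``width`` chars, never
    below ``value`` (the physical range must cover the data extrema)."""
    for prec in range(7, 0, -1):
        text = f"{value:.{prec}g}"
        if len(text) > width:
            continue
        if float(text) < value:  # round up at this precision
            step = 10.0 ** (math.floor(math.log10(abs(value))) - prec + 1)
            text = f"{float(text) + step:.{prec}g}"
            if len(text) > width or float(text) < value:
                continue
        return text
    raise ValidationError(f"cannot format {value} in {width} chars")


def _sanitize_label(label: str) -> str:
    lab = label[:16]
    if lab != label:
        warnings.warn(f"EDF label {label!r} truncated to {lab!r} (16-char field)")
    return lab


def _annotation_text(ann: PhaseAnnotation) -> str:
    return f"Phase {ann.phase.value}/{ann.condition.value}"


_ANNOT_RE = re.compile(r"Phase\s+(I{1,3}|IV|V)/(eyes_open|eyes_closed)")


def _parse_annotation_text(text: str) -> tuple[Phase, Condition] | None:
    m = _ANNOT_RE.fullmatch(text.strip())
    if not m:
        return None
    return Phase(m.group(1)), Condition(m.group(2))


def write_edf(recording: Recording, path, *, sidecar: bool = True) -> None:
    """Write a recording as EDF+ (continuous) with phase annotations.

    The physical range is symmetric about zero and covers the data
    extrema, so quantization error is at most ``range / 2**16`` per
    sample. Requires a whole number of seconds of data (the record
    duration is one second).

    Raises
    ------
    ValidationError
        For non-finite data or a sample count that is not a multiple of
        the sampling rate.
    """
    path = Path(path)
    data = recording.data
    if not np.all(np.isfinite(data)):
        raise ValidationError("cannot write non-finite samples to EDF")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedFormatError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_samples, n_channels = data.shape
    if n_samples % fs != 0:
        raise ValidationError(
            f"EDF writer needs whole-second data: {n_samples} samples at {fs} Hz"
        )
    n_records = n_samples // fs

    # physical scaling (one symmetric range for all EEG signals); the
    # range is rounded through its ASCII header representation first (7
    # chars, leaving room for the minus sign in the min field) so writer
    # and any reader use the identical gain
    absmax = float(np.max(np.abs(data))) if data.size else 0.0
    phys_text = _phys_text(max(absmax, 1e-3), 7)
    phys_max = float(phys_text)
    gain = phys_max / _DIG_MAX
    digital = np.clip(np.round(data / gain), _DIG_MIN, _DIG_MAX).astype("<i2")

    # EDF+ annotation signal: each record starts with its timestamp TAL,
    # followed by the phase annotations that begin inside it.
    record_tals: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for ann in recording.annotations:
            if r <= ann.onset < r + 1:
                tal += (
                    f"+{ann.onset:g}\x15{ann.duration:g}\x14"
                    f"{_annotation_text(ann)}\x14\x00"
                ).encode("ascii")
        record_tals.append(tal)
    annot_bytes = max(16, max(len(t) for t in record_tals))
    annot_spr = math.ceil(annot_bytes / 2)  # 2 bytes per "sample"

    labels = [_sanitize_label(lab) for lab in recording.channel_labels]
    n_signals = n_channels + 1
    header_bytes = 256 * (1 + n_signals)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))                     # patient id (EDF+)
        fh.write(_field("Startdate X X X X", 80))           # recording id (EDF+)
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_num_field(header_bytes, 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_num_field(n_records, 8))
        fh.write(_num_field(1, 8))                          # record duration, s
        fh.write(_num_field(n_signals, 4))

        sig_labels = labels + [_ANNOT_LABEL]
        for lab in sig_labels:
            fh.write(_field(lab, 16))
        for _ in sig_labels:
            fh.write(_field("", 80))                        # transducer
        for i in range(n_signals):
            fh.write(_field("uV" if i < n_channels else "", 8))
        for i in range(n_signals):
            fh.write(_field("-" + phys_text if i < n_channels else "-1", 8))
        for i in range(n_signals):
            fh.write(_field(phys_text if i < n_channels else "1", 8))
        for i in range(n_signals):
            fh.write(_num_field(_DIG_MIN if i < n_channels else -32768, 8))
        for i in range(n_signals):
            fh.write(_num_field(_DIG_MAX, 8))
        for _ in sig_labels:
            fh.write(_field("", 80))                        # prefiltering
        for i in range(n_signals):
            fh.write(_num_field(fs if i < n_channels else annot_spr, 8))
        for _ in sig_labels:
            fh.write(_field("", 32))

        for r in range(n_records):
            fh.write(digital[r * fs : (r + 1) * fs].T.tobytes())
            fh.write(record_tals[r].ljust(2 * annot_spr, b"\x00"))

    if sidecar and recording.annotations:
        write_phase_sidecar(recording.annotations, _sidecar_path(path))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".phases.json")


def write_phase_sidecar(annotations: list[PhaseAnnotation], path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_dict() for a in annotations], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_phase_sidecar(path) -> list[PhaseAnnotation]:
    with open(path) as fh:
        return [PhaseAnnotation.from_dict(d) for d in json.load(fh)]


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    All EEG signals must share one sampling rate. Phase annotations are
    taken from the EDF+ annotation channel when parseable, otherwise from
    the ``<name>.phases.json`` sidecar if present.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:  # pragma: no cover - OS specific
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(raw) < 256:
        raise FormatError(f"{path} is too short to be EDF ({len(raw)} bytes)")

    def ascii_at(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        header_bytes = int(ascii_at(184, 8))
        reserved = ascii_at(192, 44)
        n_records = int(ascii_at(236, 8))
        record_dur = float(ascii_at(244, 8))
        n_signals = int(ascii_at(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
    if n_signals <= 0 or header_bytes != 256 * (1 + n_signals):
        raise FormatError(f"{path}: inconsistent EDF header sizes")
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: truncated header")
    if reserved.startswith("EDF+D"):
        raise UnsupportedFormatError("discontinuous EDF+D files are not supported")

    # per-signal header blocks: (width, name) in file order
    _WIDTHS = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    _starts = 256 + np.concatenate([[0], np.cumsum(_WIDTHS)[:-1]]) * n_signals

    def sig_fields(idx: int) -> list[str]:
        base, width = int(_starts[idx]), _WIDTHS[idx]
        return [
            raw[base + s * width : base + (s + 1) * width]
            .decode("ascii", errors="replace")
            .strip()
            for s in range(n_signals)
        ]

    try:
        labels = sig_fields(0)
        phys_dims = sig_fields(2)
        phys_min = [float(v) for v in sig_fields(3)]
        phys_max = [float(v) for v in sig_fields(4)]
        dig_min = [int(float(v)) for v in sig_fields(5)]
        dig_max = [int(float(v)) for v in sig_fields(6)]
        spr = [int(v) for v in sig_fields(8)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF signal headers: {exc}") from exc

    eeg_idx = [i for i, lab in enumerate(labels) if lab != _ANNOT_LABEL]
    annot_idx = [i for i, lab in enumerate(labels) if lab == _ANNOT_LABEL]
    if not eeg_idx:
        raise UnsupportedFormatError(f"{path}: no data signals")
    if len({spr[i] for i in eeg_idx}) != 1:
        raise UnsupportedFormatError(
            f"{path}: heterogeneous sampling rates across signals"
        )
    if record_dur <= 0:
        raise FormatError(f"{path}: non-positive record duration")
    fs = spr[eeg_idx[0]] / record_dur

    rec_len = 2 * sum(spr)
    expected = header_bytes + n_records * rec_len
    if len(raw) < expected:
        raise FormatError(
            f"{path}: truncated data ({len(raw)} bytes, expected {expected})"
        )

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes,
                         count=n_records * rec_len // 2)
    body = body.reshape(n_records, rec_len // 2)
    offsets = np.concatenate([[0], np.cumsum(spr)])

    n_ch = len(eeg_idx)
    data = np.empty((n_records * spr[eeg_idx[0]], n_ch))
    for col, i in enumerate(eeg_idx):
        chunk = body[:, offsets[i] : offsets[i + 1]]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        sig = (chunk.astype(np.float64) - dig_min[i]) * gain + phys_min[i]
        dim = phys_dims[i].lower()
        if dim in ("uv", "µv", ""):
            pass
        elif dim == "mv":
            sig *= 1e3
        elif dim == "v":
            sig *= 1e6
        else:
            warnings.warn(f"unknown physical dimension {phys_dims[i]!r}; assuming uV")
        data[:, col] = sig.ravel()

    annotations: list[PhaseAnnotation] = []
    for i in annot_idx:
        annotations.extend(_parse_tals(body[:, offsets[i] : offsets[i + 1]]))
    if not annotations and _sidecar_path(path).exists():
        annotations = read_phase_sidecar(_sidecar_path(path))
    annotations.sort(key=lambda a: a.onset)

    return Recording(
        data=data,
        fs=fs,
        channel_labels=[labels[i] for i in eeg_idx],
        annotations=annotations,
    )


def _parse_tals(chunks: np.ndarray) -> list[PhaseAnnotation]:
    """Decode phase annotations from an EDF+ annotation signal."""
    out: list[PhaseAnnotation] = []
    for row in chunks:
        text = row.tobytes().decode("ascii", errors="replace")
        for tal in text.split("\x00"):
            if not tal or "\x14" not in tal:
                continue
            head, *descs = tal.split("\x14")
            if "\x15" in head:
                onset_s, dur_s = head.split("\x15")
            else:
                onset_s, dur_s = head, ""
            for desc in descs:
                parsed = _parse_annotation_text(desc) if desc else None
                if parsed is None:
                    continue
                try:
                    onset = float(onset_s)
                    duration = float(dur_s) if dur_s else 0.0
                except ValueError:
                    continue
                out.append(PhaseAnnotation(parsed[0], parsed[1], onset, duration))
    return out
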
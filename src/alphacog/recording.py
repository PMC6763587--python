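"""Core container for multichannel EEG recordings and phase segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MissingPhaseError, ValidationError
from .phases import Condition, Phase, PhaseAnnotation, validate_annotations

#: Reference designator for average-referenced data.
AVERAGE_REFERENCE = "average"


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Parameters
    ----------
    data:
        ``(n_samples, n_channels)`` float array, microvolts. Saturation is
        represented by rail values; NaN/inf are rejected on construction.
    fs:
        Sampling rate in samples/s (the cycling protocol records at 1024).
    channel_labels:
        Unique label per column of ``data``.
    reference:
        Physical reference label (e.g. ``"M1"``, ``"CPz"``) or
        :data:`AVERAGE_REFERENCE` after re-referencing.
    annotations:
        Ordered, non-overlapping phase annotations.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "unknown"
    annotations: list[PhaseAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D, got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValidationError(
                f"{self.data.shape[1]} data columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")
        validate_annotations(self.annotations)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        """Return a copy with some fields replaced (data is not copied unless given)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StudyLayout:
    """Bookkeeping for one recording session within a two-cap study."""

    subject_id: str
    cap_type: str  # "gel" | "dry"
    phase: Phase
    path: str | None = None

    def __post_init__(self) -> None:
        if self.cap_type not in ("gel", "dry"):
            raise ValidationError(f"cap_type must be 'gel' or 'dry', got {self.cap_type!r}")


def segment_by_phase(
    recording: Recording,
) -> dict[tuple[Phase, Condition], Recording]:
    """Split a recording into per-phase sub-recordings.

    Each annotation yields one segment whose sample count is exactly
    ``round(duration * fs)``; the baseline phase therefore yields separate
    eyes-open and eyes-closed segments. Segments carry a single annotation
    re-based to onset 0.

    Raises
    ------
    ValidationError
        If annotations overlap or run past the end of the recording.
    MissingPhaseError
        If the recording has no annotations at all.
    """
    if not recording.annotations:
        raise MissingPhaseError("recording has no phase annotations")
    validate_annotations(recording.annotations)
    out: dict[tuple[Phase, Condition], Recording] = {}
    for ann in recording.annotations:
        start = int(round(ann.onset * recording.fs))
        n = int(round(ann.duration * recording.fs))
        if start + n > recording.n_samples:
            raise ValidationError(
                f"annotation {ann.phase}/{ann.condition} ends at sample "
                f"{start + n}, beyond recording length {recording.n_samples}"
            )
        key = (ann.phase, ann.condition)
        if key in out:
            raise ValidationError(f"duplicate annotation for {ann.phase}/{ann.condition}")
        out[key] = Recording(
            data=recording.data[start : start + n],
            fs=recording.fs,
            channel_labels=list(recording.channel_labels),
            reference=recording.reference,
            annotations=[
                PhaseAnnotation(ann.phase, ann.condition, 0.0, ann.duration)
            ],
        )
    return out


def get_phase_segment(
    recording: Recording, phase: Phase, condition: Condition | None = None
) -> Recording:
    """Return the segment for ``phase`` (and ``condition`` if given)."""
    segments = segment_by_phase(recording)
    matches = [
        seg
        for (ph, cond), seg in segments.items()
        if ph is phase and (condition is None or cond is condition)
    ]
    if not matches:
        raise MissingPhaseError(f"no annotation for phase {phase}" +
                                (f"/{condition}" if condition else ""))
    if len(matches) > 1:
        raise ValidationError(
            f"phase {phase} has multiple conditions; pass condition explicitly"
        )
    return matches[0]
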
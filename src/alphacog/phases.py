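"""Paradigm phases of the five-phase endurance-cycling protocol.

The protocol has five sequential phases: (I) seated baseline with 2 min
eyes open followed by 2 min eyes closed, (II) 2 min pre-cycling rest on
the ergometer with eyes closed, (III) incremental cycling to exhaustion
(duration varies per person), (IV) 2 min active recovery at low load with
eyes closed, and (V) 2 min passive recovery with eyes closed. Spectral
statistics are computed for Phases II, IV and V; Phases I and III are
processed for quality control and spectra only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ValidationError


class Phase(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Condition(enum.Enum):
    EYES_OPEN = "eyes_open"
    EYES_CLOSED = "eyes_closed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Phases whose whole-head iAPF enters the inferential analysis.
ANALYZED_PHASES = (Phase.II, Phase.IV, Phase.V)

#: Default duration (s) of each fixed-length segment; Phase III is free in
#: the protocol (roughly 6-28 min of cycling) and is scaled to 120 s here
#: so a full synthetic study stays desk-sized.
DEFAULT_DURATIONS = {
    (Phase.I, Condition.EYES_OPEN): 120.0,
    (Phase.I, Condition.EYES_CLOSED): 120.0,
    (Phase.II, Condition.EYES_CLOSED): 120.0,
    (Phase.III, Condition.EYES_OPEN): 120.0,
    (Phase.IV, Condition.EYES_CLOSED): 120.0,
    (Phase.V, Condition.EYES_CLOSED): 120.0,
}


@dataclass(frozen=True)
class PhaseAnnotation:
    """One labelled stretch of a recording: phase, eye condition, timing.

    Intervals are half-open ``[onset, onset + duration)`` in seconds from
    recording start; sample indices are 0-based.
    """

    phase: Phase
    condition: Condition
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValidationError(
                f"annotation {self.phase}/{self.condition}: onset must be >= 0 "
                f"and duration > 0 (got onset={self.onset}, duration={self.duration})"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def to_dict(self) -> dict:
        return {
            "phase": self.phase.value,
            "condition": self.condition.value,
            "onset": self.onset,
            "duration": self.duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseAnnotation":
        return cls(
            phase=Phase(d["phase"]),
            condition=Condition(d["condition"]),
            onset=float(d["onset"]),
            duration=float(d["duration"]),
        )


def validate_annotations(annotations: list[PhaseAnnotation]) -> None:
    """Check that annotations are ordered and non-overlapping."""
    for a, b in zip(annotations, annotations[1:]):
        if b.onset < a.end - 1e-9:
            raise ValidationError(
                f"annotations overlap or are unordered: {a.phase}/{a.condition} "
                f"[{a.onset}, {a.end}) vs {b.phase}/{b.condition} [{b.onset}, {b.end})"
            )
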
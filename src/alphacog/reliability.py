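"""Channel-reliability percentages and per-electrode grand averages.

Channel reliability is the usability metric of the cap comparison: the
percentage of channels retained after bad-channel exclusion, per subject,
cap and phase. Topographic grand averages (reliability fractions, or
ingested impedance tables in kOhm) are exported as plotting-ready tables
keyed by electrode label; the package does not render head plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import ChannelQC


@dataclass(frozen=True)
class ReliabilityRecord:
    """Retained-channel percentage for one subject x cap x phase."""

    subject_id: str
    cap_type: str
    phase: str
    n_channels_total: int
    n_channels_retained: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_channels_retained <= self.n_channels_total:
            raise ValidationError("retained count out of range")

    @property
    def reliability_exact(self) -> Fraction:
        """Exact rational percentage (rounded only for display)."""
        return Fraction(100 * self.n_channels_retained, self.n_channels_total)

    @property
    def reliability(self) -> float:
        return float(self.reliability_exact)


def channel_reliability(
    qc: ChannelQC, *, subject_id: str = "", cap_type: str = "", phase: str = ""
) -> ReliabilityRecord:
    """Percentage of retained channels after bad-channel exclusion."""
    return ReliabilityRecord(
        subject_id=subject_id,
        cap_type=cap_type,
        phase=phase,
        n_channels_total=len(qc.labels),
        n_channels_retained=qc.n_good,
    )


def topographic_grand_average(records: pd.DataFrame) -> pd.DataFrame:
    """Per-electrode mean and population STD of a scalar across subjects.

    ``records``: rows = observations (subject, or subject x phase),
    columns = electrode labels, values = the scalar (reliability fraction,
    impedance in kOhm, ...). Missing entries (excluded sessions) are
    omitted pairwise; the returned frame reports the per-electrode count.

    The STD is the population (n) form — a descriptive display statistic.
    """
    if not isinstance(records, pd.DataFrame):
        raise ValidationError("records must be a pandas DataFrame")
    if records.shape[1] == 0:
        raise ValidationError("no electrodes in records")
    mean = records.mean(axis=0, skipna=True)
    std = records.std(axis=0, ddof=0, skipna=True)
    count = records.notna().sum(axis=0)
    out = pd.DataFrame({"mean": mean, "std": std, "n": count})
    out.index.name = "electrode"
    return out


def reliability_table(records: list[ReliabilityRecord]) -> pd.DataFrame:
    """Long-format table of reliability records."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "cap_type": r.cap_type,
                "phase": r.phase,
                "n_channels_total": r.n_channels_total,
                "n_channels_retained": r.n_channels_retained,
                "reliability_percent": r.reliability,
            }
            for r in records
        ]
    )


def per_electrode_good_fraction(
    qcs: list[ChannelQC], labels: list[str]
) -> np.ndarray:
    """Fraction of segments in which each electrode was good."""
    if not qcs:
        raise ValidationError("no QC records")
    acc = np.zeros(len(labels))
    for qc in qcs:
        if qc.labels != labels:
            raise ValidationError("QC label sets differ across records")
        acc += qc.good_mask
    return acc / len(qcs)
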
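"""End-to-end study analysis: segment -> QC -> filter -> re-reference ->
interpolate -> Welch -> presence gate -> iAPF -> RM-ANOVA.

The pipeline runs per subject x cap x phase unit; a failure in one unit
is recorded and does not abort the study. Subjects without considerable
alpha activity (presence ratio < 1.3) in one or more gate phases are
dropped entirely before inference; the analysis needs at least three
complete subjects.

Input is either a study directory written by
:func:`alphacog.synth.synthesize_study` (EDF + sidecars + montages) or a
:class:`alphacog.synth.SynthStudyConfig` for in-memory generation (no
disk round-trip; bit-identical to analyzing the written study up to EDF
quantization).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import AlphacogError, InsufficientSubjectsError
from .montage import Montage, load_montage
from .phases import ANALYZED_PHASES, Condition, Phase
from .preprocessing import (
    ChannelQC,
    FilterSpec,
    QCThresholds,
    average_reference,
    bandpass,
    detect_bad_channels,
    interpolate_bad,
)
from .recording import Recording, segment_by_phase
from .reliability import ReliabilityRecord, channel_reliability, reliability_table
from .spectral import (
    PRESENCE_THRESHOLD,
    AlphaMetrics,
    analyze_mean_spectrum,
    mean_psd,
    welch_psd,
)
from .stats import AnovaReport, long_to_wide, rm_anova_2x3
from .synth import SynthStudyConfig, iter_study, study_montage

#: Phases whose alpha presence gates subject inclusion: the analyzed
#: phases plus the closed-eye baseline.
DEFAULT_GATE = (
    (Phase.I, Condition.EYES_CLOSED),
    (Phase.II, Condition.EYES_CLOSED),
    (Phase.IV, Condition.EYES_CLOSED),
    (Phase.V, Condition.EYES_CLOSED),
)


@dataclass
class PipelineConfig:
    """All pipeline knobs with the analysis-protocol defaults."""

    study_dir: str | None = None
    synth: SynthStudyConfig | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    welch_win_seconds: float = 4.0
    welch_overlap: float = 0.5
    presence_threshold: float = PRESENCE_THRESHOLD
    analyzed_phases: tuple[Phase, ...] = ANALYZED_PHASES
    gate: tuple[tuple[Phase, Condition], ...] = DEFAULT_GATE
    min_subjects: int = 3

    def provenance(self) -> dict:
        blob = json.dumps(
            {
                "study_dir": self.study_dir,
                "synth_seed": self.synth.seed if self.synth else None,
                "filter": [self.filter_spec.order, *self.filter_spec.band],
                "welch": [self.welch_win_seconds, self.welch_overlap],
                "presence_threshold": self.presence_threshold,
                "analyzed_phases": [p.value for p in self.analyzed_phases],
            },
            sort_keys=True,
        )
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "alphacog_version": __version__,
            "seed": self.synth.seed if self.synth else None,
        }


@dataclass
class UnitResult:
    """Outcome of one subject x cap x phase/condition unit."""

    subject_id: str
    cap_type: str
    phase: Phase
    condition: Condition
    qc: ChannelQC | None = None
    reliability: ReliabilityRecord | None = None
    alpha: AlphaMetrics | None = None
    error: str | None = None


@dataclass
class StudyReport:
    """Aggregated study outcome (regenerable bit-identically from config)."""

    units: list[UnitResult]
    iapf_long: pd.DataFrame
    excluded_subjects: dict[str, str]
    analyzed_subjects: list[str]
    anova: AnovaReport | None
    provenance: dict

    def iapf_grand_means(self) -> pd.DataFrame:
        """Mean and sample STD of iAPF per cap x phase over analyzed subjects."""
        g = self.iapf_long.groupby(["cap", "phase"])["iapf"]
        return g.agg(mean="mean", std="std", n="count").reset_index()

    def reliability_long(self) -> pd.DataFrame:
        recs = [u.reliability for u in self.units if u.reliability is not None]
        return reliability_table(recs)

    def to_json(self, indent: int | None = 1) -> str:
        payload = {
            "provenance": self.provenance,
            "excluded_subjects": dict(sorted(self.excluded_subjects.items())),
            "analyzed_subjects": list(self.analyzed_subjects),
            "iapf": [
                {k: (v.value if isinstance(v, Phase) else v) for k, v in row.items()}
                for row in self.iapf_long.to_dict("records")
            ],
            "grand_means": self.iapf_grand_means().to_dict("records"),
            "reliability": self.reliability_long().to_dict("records"),
            "anova": self.anova.to_dict() if self.anova else None,
            "units": [
                {
                    "subject_id": u.subject_id,
                    "cap_type": u.cap_type,
                    "phase": u.phase.value,
                    "condition": u.condition.value,
                    "n_good": u.qc.n_good if u.qc else None,
                    "bad_channels": sorted(u.qc.bad_labels) if u.qc else None,
                    "presence_ratio": u.alpha.presence_ratio if u.alpha else None,
                    "alpha_present": u.alpha.alpha_present if u.alpha else None,
                    "iapf": u.alpha.iapf if u.alpha else None,
                    "error": u.error,
                }
                for u in self.units
            ],
        }
        return json.dumps(payload, indent=indent, sort_keys=True,
                          allow_nan=True, default=float)


def process_segment(
    segment: Recording,
    montage: Montage,
    config: PipelineConfig,
) -> tuple[ChannelQC, AlphaMetrics]:
    """QC, filter, re-reference, interpolate and gate one phase segment."""
    qc = detect_bad_channels(segment, config.qc_thresholds)
    rec = bandpass(segment, config.filter_spec)
    rec = average_reference(rec, qc)
    rec = interpolate_bad(rec, qc, montage)
    spectral = welch_psd(
        rec,
        win_seconds=config.welch_win_seconds,
        overlap=config.welch_overlap,
    )
    metrics = analyze_mean_spectrum(
        spectral.freqs, mean_psd(spectral),
        threshold=config.presence_threshold,
    )
    return qc, metrics


def _iter_sessions(config: PipelineConfig):
    """Yield (subject_id, cap, montage, recording) per session recording."""
    if config.synth is not None:
        for subject_id, cap, session in iter_study(config.synth):
            montage = study_montage(cap)
            for rec, _truth in session:
                if rec is not None:
                    yield subject_id, cap, montage, rec
    elif config.study_dir is not None:
        from .edf import read_edf

        root = Path(config.study_dir)
        montages = {
            cap: load_montage(root / f"montage_{cap}.tsv", layout_kind=cap)
            for cap in ("dry", "gel")
            if (root / f"montage_{cap}.tsv").exists()
        }
        for subj_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for cap_dir in sorted(p for p in subj_dir.iterdir() if p.is_dir()):
                cap = cap_dir.name
                for edf_path in sorted(cap_dir.glob("*.edf")):
                    yield subj_dir.name, cap, montages[cap], read_edf(edf_path)
    else:
        raise AlphacogError("PipelineConfig needs either study_dir or synth")


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run the full study analysis and inferential statistics.

    Per-unit errors are captured in the report; the run only fails
    globally when fewer than ``min_subjects`` complete subjects remain.
    """
    units: list[UnitResult] = []
    # (subject, cap, phase, condition) -> AlphaMetrics
    gate_metrics: dict[tuple[str, str, Phase, Condition], AlphaMetrics] = {}
    subjects: list[str] = []

    for subject_id, cap, montage, recording in _iter_sessions(config):
        if subject_id not in subjects:
            subjects.append(subject_id)
        for (phase, condition), segment in segment_by_phase(recording).items():
            unit = UnitResult(subject_id, cap, phase, condition)
            try:
                qc, metrics = process_segment(segment, montage, config)
                unit.qc = qc
                unit.reliability = channel_reliability(
                    qc, subject_id=subject_id, cap_type=cap, phase=phase.value
                )
                unit.alpha = metrics
            except AlphacogError as exc:
                unit.error = f"{type(exc).__name__}: {exc}"
            units.append(unit)
            if unit.alpha is not None:
                gate_metrics[(subject_id, cap, phase, condition)] = unit.alpha

    excluded: dict[str, str] = {}
    caps = sorted({u.cap_type for u in units})
    for subject_id in subjects:
        reasons = []
        for cap in caps:
            for phase, condition in config.gate:
                m = gate_metrics.get((subject_id, cap, phase, condition))
                if m is None:
                    reasons.append(f"{cap}/phase {phase.value}: unavailable")
                elif not m.alpha_present:
                    reasons.append(
                        f"{cap}/phase {phase.value}: presence ratio "
                        f"{m.presence_ratio:.2f} < {config.presence_threshold}"
                    )
            for phase in config.analyzed_phases:
                m = gate_metrics.get((subject_id, cap, phase, Condition.EYES_CLOSED))
                if m is not None and m.alpha_present and m.iapf is None:
                    reasons.append(f"{cap}/phase {phase.value}: no iAPF")
        if reasons:
            excluded[subject_id] = "no considerable alpha activity: " + "; ".join(
                reasons
            )
    analyzed = [s for s in subjects if s not in excluded]

    rows = []
    for (subject_id, cap, phase, condition), m in gate_metrics.items():
        if (
            subject_id in excluded
            or phase not in config.analyzed_phases
            or m.iapf is None
        ):
            continue
        rows.append(
            {"subject": subject_id, "cap": cap, "phase": phase.value,
             "iapf": m.iapf}
        )
    iapf_long = pd.DataFrame(rows, columns=["subject", "cap", "phase", "iapf"])

    anova = None
    if len(analyzed) < config.min_subjects:
        raise InsufficientSubjectsError(
            f"only {len(analyzed)} subjects pass the alpha criterion "
            f"(need {config.min_subjects}); excluded: {excluded}"
        )
    wide = long_to_wide(iapf_long)
    complete = wide.dropna()
    if len(complete) >= config.min_subjects and complete.shape[1] == 6:
        anova = rm_anova_2x3(complete)

    return StudyReport(
        units=units,
        iapf_long=iapf_long,
        excluded_subjects=excluded,
        analyzed_subjects=analyzed,
        anova=anova,
        provenance=config.provenance(),
    )
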
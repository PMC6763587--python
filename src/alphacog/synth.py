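"""Synthetic five-phase cycling study generator with exact ground truth.

The generator emulates the two-cap endurance-cycling protocol: per
subject, per cap, per phase recordings whose whole-head mean spectrum has
a *known* alpha-band center of gravity, together with injected channel
failures (isoelectric, saturated, artifactual) at phase-dependent rates
and Poisson-timed movement-artifact bursts.

Signal model per channel::

    x_c(t) = w_c * a(t) + b_c(t) + bursts_c(t) + failures

* ``a(t)`` is band-filtered Gaussian noise with a symmetric (cosine^2)
  spectral envelope centred at ``f_alpha`` — symmetric, so its band
  center of gravity is exactly ``f_alpha``. Modeling alpha as filtered
  noise (not a sinusoid) keeps the center of gravity a nondegenerate
  functional of a continuous spectrum.
* ``w_c`` is a posterior-to-anterior spatial gradient, demeaned across
  channels (dipolar-like, so average re-referencing leaves the alpha
  component intact) and normalized to unit mean square (so the
  whole-head mean alpha PSD equals the configured peak density).
* ``b_c(t)`` is independent 1/f^beta background noise per channel.

Because the 1/f background is not flat across the alpha band, it pulls
the band center of gravity below the alpha center. The generator cancels
this analytically: given the configured target iAPF it solves for the
alpha center ``f_alpha`` such that the center of gravity of the *total*
mean spectrum equals the target. The per-recording ground truth is
therefore exact, not approximate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .montage import Montage, equidistant_64, save_montage, tentwenty_64
from .phases import ANALYZED_PHASES, Condition, Phase, PhaseAnnotation
from .preprocessing import ARTIFACTUAL, ISOELECTRIC, SATURATED
from .recording import Recording
from .spectral import ALPHA_BAND

#: Rail value (µV) used for injected saturation.
RAIL_UV = 400.0

#: Eyes-open / eyes-closed alpha power contrast (closed-eye peak density
#: of 7.8 µV²/Hz vs open-eye 2.25 µV²/Hz in the grand-average spectra).
EYES_OPEN_POWER_SCALE = 2.25 / 7.8


# --------------------------------------------------------------------------
# low-level signal factories

def make_background(
    n_samples: int,
    fs: float,
    exponent: float,
    scale: float = 2.0,
    seed=None,
) -> np.ndarray:
    """Zero-mean 1/f^exponent noise; ``scale`` is the one-sided PSD at 10 Hz
    (µV²/Hz). The spectral shape is flattened below 1 Hz to keep finite
    power; over 1-40 Hz the log-log PSD slope is ``-exponent``."""
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if not 0 <= exponent <= 2:
        raise ConfigurationError(f"exponent must be in [0, 2], got {exponent}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaped = np.maximum(freqs, 1.0)
    mask = np.sqrt(scale * fs / 2.0) * (shaped / 10.0) ** (-exponent / 2.0)
    mask[0] = 0.0  # zero mean
    return np.fft.irfft(spec * mask, n=n_samples)


def make_alpha(
    n_samples: int,
    fs: float,
    f0: float,
    bandwidth: float,
    amplitude: float,
    seed=None,
    *,
    band_limits: tuple[float, float] = ALPHA_BAND,
) -> np.ndarray:
    """Narrowband noise with a cosine^2 PSD envelope centred at ``f0``.

    ``amplitude`` is the peak one-sided PSD (µV²/Hz); the envelope is
    symmetric about ``f0``, so the center of gravity of its spectrum over
    the alpha band equals ``f0`` exactly. The passband
    ``[f0 - bw/2, f0 + bw/2]`` must lie inside the alpha band.
    """
    lo, hi = f0 - bandwidth / 2.0, f0 + bandwidth / 2.0
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    if lo < band_limits[0] or hi > band_limits[1]:
        raise ConfigurationError(
            f"alpha passband [{lo:.2f}, {hi:.2f}] exceeds {band_limits}"
        )
    if amplitude == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    envelope = np.where(
        np.abs(freqs - f0) <= bandwidth / 2.0,
        np.cos(np.pi * (freqs - f0) / bandwidth),
        0.0,
    )
    mask = np.sqrt(amplitude * fs / 2.0) * envelope
    return np.fft.irfft(spec * mask, n=n_samples)


def posterior_weights(montage: Montage) -> np.ndarray:
    """Alpha topography: stronger over parieto-occipital channels.

    A linear anterior->posterior gradient of the unit-sphere y coordinate,
    demeaned across channels and scaled to unit mean square.
    """
    y = montage.positions[:, 1]
    w = (1.0 - y) / 2.0
    w = w - w.mean()
    rms = np.sqrt((w**2).mean())
    if rms == 0:  # degenerate montage (all channels at one point)
        return np.ones(len(montage))
    return w / rms


# --------------------------------------------------------------------------
# analytic spectrum bookkeeping

def background_band_power(
    scale: float, exponent: float, band: tuple[float, float]
) -> tuple[float, float]:
    """In-band power and center of gravity of the 1/f^beta background.

    Returns ``(power, cog)`` for S(f) = scale * (f/10)^-beta over the band.
    """
    lo, hi = band
    if exponent == 1.0:
        power = scale * 10.0 * np.log(hi / lo)
        cog = (hi - lo) / np.log(hi / lo)
    else:
        b = exponent
        c = scale * 10.0**b
        power = c * (hi ** (1 - b) - lo ** (1 - b)) / (1 - b)
        if b == 2.0:
            num = c * np.log(hi / lo)
        else:
            num = c * (hi ** (2 - b) - lo ** (2 - b)) / (2 - b)
        cog = num / power
    return power, cog


def compensated_alpha_center(
    target: float,
    alpha_peak_psd: float,
    bandwidth: float,
    bg_scale: float,
    bg_exponent: float,
    n_channels: int,
    *,
    coherence: float = 0.5,
    band: tuple[float, float] = ALPHA_BAND,
    margin: float = 0.05,
) -> tuple[float, float]:
    """Alpha center whose *total* spectrum band-COG equals ``target``.

    The average reference scales the channel-independent signal parts by
    ``(n-1)/n`` while leaving the shared (demeaned-topography) alpha part
    intact; both the in-band background power and the incoherent alpha
    fraction are corrected accordingly. Returns ``(f_alpha,
    realized_cog)``; when the compensation would push the passband
    outside the alpha band, the center is clamped and the realized
    (analytic) center of gravity is returned alongside.
    """
    ref_factor = (n_channels - 1) / n_channels
    p_alpha = alpha_peak_psd * bandwidth / 2.0
    p_alpha *= coherence + (1.0 - coherence) * ref_factor
    p_bg, mu_bg = background_band_power(bg_scale, bg_exponent, band)
    p_bg *= ref_factor
    f_alpha = target + (p_bg / p_alpha) * (target - mu_bg)
    lo = band[0] + bandwidth / 2.0 + margin
    hi = band[1] - bandwidth / 2.0 - margin
    f_alpha = float(np.clip(f_alpha, lo, hi))
    realized = (p_alpha * f_alpha + p_bg * mu_bg) / (p_alpha + p_bg)
    return f_alpha, float(realized)


# --------------------------------------------------------------------------
# phase/study configuration

@dataclass(frozen=True)
class SynthPhaseSpec:
    """Ground-truth parameters of one synthetic phase segment."""

    phase: Phase
    condition: Condition
    duration: float              # s
    true_iapf: float             # Hz, target whole-head band COG
    alpha_bandwidth: float = 2.0  # Hz, full width of the cos^2 envelope
    alpha_power_scale: float = 1.0  # multiplies the closed-eye peak density
    alpha_peak_psd: float = 7.8  # µV²/Hz at eyes closed, whole-head mean
    alpha_coherence: float = 0.5  # shared-power fraction of the alpha rhythm
    background_exponent: float = 1.0
    background_scale: float = 2.0  # µV²/Hz at 10 Hz
    artifact_burst_rate: float = 0.5  # events/min/channel
    bad_channel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not ALPHA_BAND[0] < self.true_iapf < ALPHA_BAND[1]:
            raise ConfigurationError(
                f"true_iapf must lie inside {ALPHA_BAND}, got {self.true_iapf}"
            )
        if self.alpha_bandwidth <= 0:
            raise ConfigurationError("alpha_bandwidth must be positive")
        if self.artifact_burst_rate < 0 or self.bad_channel_rate < 0:
            raise ConfigurationError("rates must be nonnegative")
        if self.bad_channel_rate >= 1:
            raise ConfigurationError("bad_channel_rate must be < 1")


#: Phase-wise mean iAPF (Hz) per cap: the fatigue-shift study conditions.
TRUE_IAPF = {
    "dry": {Phase.II: 10.22, Phase.IV: 10.36, Phase.V: 10.41},
    "gel": {Phase.II: 10.23, Phase.IV: 10.37, Phase.V: 10.43},
}

#: Expected fraction of failed channels per cap and phase, mirroring the
#: reported channel-reliability percentages (dry 80/66/91 % in Phases
#: I/III/V; gel 95/85/82 %), with Phases II/IV interpolated.
BAD_CHANNEL_RATE = {
    "dry": {Phase.I: 0.20, Phase.II: 0.15, Phase.III: 0.34, Phase.IV: 0.12,
            Phase.V: 0.09},
    "gel": {Phase.I: 0.05, Phase.II: 0.08, Phase.III: 0.15, Phase.IV: 0.16,
            Phase.V: 0.18},
}

#: Movement-artifact burst rate (events/min/channel); cycling is burstier.
ARTIFACT_RATE = {
    "dry": {Phase.III: 8.0, "other": 0.6},
    "gel": {Phase.III: 4.0, "other": 0.3},
}

#: Electrode-skin impedance (kOhm) mean/SD at the start and the end of a
#: session. Dry multipin contacts start high and drop with sweating; gel
#: electrodes are prepared below a 30 kOhm threshold.
IMPEDANCE_KOHM = {
    "dry": {"start": (455.0, 251.0), "end": (132.0, 126.0)},
    "gel": {"start": (15.0, 7.0), "end": (18.0, 7.0)},
}


def synth_impedances(cap: str, montage: Montage, rng: np.random.Generator) -> dict:
    """Per-electrode start/end impedance tables (kOhm) for one session.

    Values are normal draws truncated at 1 kOhm; impedances are study
    metadata to aggregate (never used for channel rejection).
    """
    out: dict[str, dict[str, float]] = {}
    for when in ("start", "end"):
        mean, sd = IMPEDANCE_KOHM[cap][when]
        vals = np.maximum(rng.normal(mean, sd, len(montage)), 1.0)
        out[when] = {
            lab: round(float(v), 1) for lab, v in zip(montage.labels, vals)
        }
    return out


def default_phase_specs(
    cap: str,
    *,
    phase3_duration: float = 120.0,
    clean: bool = False,
) -> list[SynthPhaseSpec]:
    """The five-phase schedule for one cap with protocol durations.

    Phase I: 2 min eyes open + 2 min eyes closed; Phases II/IV/V: 2 min
    eyes closed; Phase III duration is free in the protocol (cycling to
    exhaustion) and defaults to 120 s at desk scale. ``clean=True`` zeroes
    failure and burst rates (for parameter-recovery checks).
    """
    iapf = TRUE_IAPF[cap]
    phase_iapf = {
        Phase.I: iapf[Phase.II],
        Phase.II: iapf[Phase.II],
        Phase.III: iapf[Phase.IV],
        Phase.IV: iapf[Phase.IV],
        Phase.V: iapf[Phase.V],
    }
    schedule = [
        (Phase.I, Condition.EYES_OPEN, 120.0),
        (Phase.I, Condition.EYES_CLOSED, 120.0),
        (Phase.II, Condition.EYES_CLOSED, 120.0),
        (Phase.III, Condition.EYES_OPEN, phase3_duration),
        (Phase.IV, Condition.EYES_CLOSED, 120.0),
        (Phase.V, Condition.EYES_CLOSED, 120.0),
    ]
    specs = []
    for phase, condition, duration in schedule:
        rate = ARTIFACT_RATE[cap][Phase.III if phase is Phase.III
                                  else "other"]
        specs.append(
            SynthPhaseSpec(
                phase=phase,
                condition=condition,
                duration=duration,
                true_iapf=phase_iapf[phase],
                alpha_power_scale=(
                    1.0 if condition is Condition.EYES_CLOSED
                    else EYES_OPEN_POWER_SCALE
                ),
                artifact_burst_rate=0.0 if clean else rate,
                bad_channel_rate=0.0 if clean else BAD_CHANNEL_RATE[cap][phase],
            )
        )
    return specs


@dataclass(frozen=True)
class SynthStudyConfig:
    """Full-study generator settings (defaults are the study conditions).

    17 volunteers, two caps each, subject-level iAPF offsets with 0.26 Hz
    SD, and 4 volunteers generated with sub-threshold alpha in at least
    one analyzed phase (so 13 enter the inferential analysis).
    """

    n_subjects: int = 17
    cap_types: tuple[str, ...] = ("dry", "gel")
    subject_effect_sd: float = 0.26
    n_excluded_no_alpha: int = 4
    seed: int = 0
    fs: float = 1024.0
    phase3_duration: float = 120.0
    #: multiplies every phase duration; < 1 only for desk-scale smoke runs,
    #: the protocol durations themselves stay the default
    duration_scale: float = 1.0
    clean: bool = False
    deficient_alpha_scale: float = 0.05
    phases: tuple[Phase, ...] = (Phase.I, Phase.II, Phase.III, Phase.IV, Phase.V)

    def __post_init__(self) -> None:
        if self.n_excluded_no_alpha > self.n_subjects:
            raise ConfigurationError("cannot exclude more subjects than exist")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")


@dataclass
class GroundTruth:
    """What the generator actually put into one phase recording."""

    subject_id: str
    cap_type: str
    phase: Phase
    condition: Condition
    target_iapf: float           # configured phase mean + subject offset
    realized_iapf: float         # analytic COG of the generated mean spectrum
    alpha_power_scale: float
    alpha_deficient: bool
    bad_channels: dict[str, str]  # label -> failure class

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "cap_type": self.cap_type,
            "phase": self.phase.value,
            "condition": self.condition.value,
            "target_iapf": self.target_iapf,
            "realized_iapf": self.realized_iapf,
            "alpha_power_scale": self.alpha_power_scale,
            "alpha_deficient": self.alpha_deficient,
            "bad_channels": dict(sorted(self.bad_channels.items())),
        }


# --------------------------------------------------------------------------
# recording-level synthesis

def synthesize_recording(
    phase_spec: SynthPhaseSpec,
    montage: Montage,
    subject_offset: float = 0.0,
    seed=None,
    *,
    subject_id: str = "sub-00",
    cap_type: str = "dry",
    fs: float = 1024.0,
) -> tuple[Recording, GroundTruth]:
    """Generate one phase segment plus its ground truth.

    The whole-head mean spectrum's alpha-band center of gravity equals
    ``true_iapf + subject_offset`` analytically (clamping aside, which is
    reported via ``realized_iapf``). Injected channel failures follow the
    QC definitions: isoelectric (constant), saturated (rail-pinned for
    >30 s), artifactual (high-amplitude broadband for >30 s).
    """
    rng = np.random.default_rng(seed)
    return _synthesize(phase_spec, montage, subject_offset, rng,
                       subject_id=subject_id, cap_type=cap_type, fs=fs)


def _synthesize(
    phase_spec: SynthPhaseSpec,
    montage: Montage,
    subject_offset: float,
    rng: np.random.Generator,
    *,
    subject_id: str,
    cap_type: str,
    fs: float,
    onset: float = 0.0,
) -> tuple[Recording, GroundTruth]:
    n = int(round(phase_spec.duration * fs))
    n_ch = len(montage)
    target = phase_spec.true_iapf + subject_offset
    amplitude = phase_spec.alpha_peak_psd * phase_spec.alpha_power_scale

    # independent 1/f background per channel (vectorized over channels)
    white = rng.standard_normal((n_ch, n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaped = np.maximum(freqs, 1.0)
    bg_mask = np.sqrt(phase_spec.background_scale * fs / 2.0) * (
        shaped / 10.0
    ) ** (-phase_spec.background_exponent / 2.0)
    bg_mask[0] = 0.0
    data = np.fft.irfft(np.fft.rfft(white, axis=1) * bg_mask, n=n, axis=1)
    bg_std = float(data.std())

    if amplitude > 0:
        rho = phase_spec.alpha_coherence
        f_alpha, realized = compensated_alpha_center(
            target,
            amplitude,
            phase_spec.alpha_bandwidth,
            phase_spec.background_scale,
            phase_spec.background_exponent,
            n_ch,
            coherence=rho,
        )
        # partially coherent alpha: one rhythm shared by all channels plus
        # an independent component per channel, same symmetric envelope
        shared = make_alpha(
            n, fs, f_alpha, phase_spec.alpha_bandwidth, amplitude,
            seed=rng.integers(2**31),
        )
        w = posterior_weights(montage)
        data += np.sqrt(rho) * w[:, None] * shared[None, :]
        if rho < 1.0:
            env = np.where(
                np.abs(freqs - f_alpha) <= phase_spec.alpha_bandwidth / 2.0,
                np.cos(np.pi * (freqs - f_alpha) / phase_spec.alpha_bandwidth),
                0.0,
            )
            a_mask = np.sqrt((1.0 - rho) * amplitude * fs / 2.0) * env
            indep = np.fft.irfft(
                np.fft.rfft(rng.standard_normal((n_ch, n)), axis=1) * a_mask,
                n=n, axis=1,
            )
            data += w[:, None] * indep
    else:
        _, realized = 0.0, background_band_power(
            phase_spec.background_scale, phase_spec.background_exponent,
            ALPHA_BAND,
        )[1]

    # Poisson-timed movement-artifact bursts, per channel
    if phase_spec.artifact_burst_rate > 0:
        expected = phase_spec.artifact_burst_rate * phase_spec.duration / 60.0
        for ch in range(n_ch):
            for _ in range(rng.poisson(expected)):
                dur = rng.uniform(0.5, 3.0)
                start = rng.uniform(0.0, max(phase_spec.duration - dur, 0.0))
                i0 = int(start * fs)
                i1 = min(n, i0 + int(dur * fs))
                data[ch, i0:i1] += rng.standard_normal(i1 - i0) * 5.0 * bg_std

    # channel failures
    bad: dict[str, str] = {}
    if phase_spec.bad_channel_rate > 0:
        fail_mask = rng.random(n_ch) < phase_spec.bad_channel_rate
        # failures must persist > 30 s to meet the QC definition; segments
        # shorter than that (desk-scale smoke runs) fail for most of their
        # duration instead
        min_fail = min(31.0, 0.6 * phase_spec.duration)
        max_fail = max(min_fail + 0.5, 0.45 * phase_spec.duration)
        for ch in np.flatnonzero(fail_mask):
            kind = rng.choice([ISOELECTRIC, SATURATED, ARTIFACTUAL])
            label = montage.labels[ch]
            bad[label] = str(kind)
            if kind == ISOELECTRIC:
                data[ch] = rng.uniform(-5, 5)
            elif kind == SATURATED:
                dur = rng.uniform(min_fail, max_fail)
                start = rng.uniform(0.0, phase_spec.duration - dur)
                i0, i1 = int(start * fs), min(n, int((start + dur) * fs))
                sign = rng.choice([-1.0, 1.0])
                ripple = np.abs(rng.standard_normal(i1 - i0)) * 0.5
                data[ch, i0:i1] = sign * (RAIL_UV - ripple)
            else:  # artifactual
                dur = rng.uniform(min_fail, max_fail)
                start = rng.uniform(0.0, phase_spec.duration - dur)
                i0, i1 = int(start * fs), min(n, int((start + dur) * fs))
                data[ch, i0:i1] += rng.standard_normal(i1 - i0) * 8.0 * bg_std

    np.clip(data, -RAIL_UV, RAIL_UV, out=data)
    rec = Recording(
        data=np.ascontiguousarray(data.T),
        fs=fs,
        channel_labels=list(montage.labels),
        reference="M1" if cap_type == "dry" else "CPz",
        annotations=[
            PhaseAnnotation(phase_spec.phase, phase_spec.condition, onset,
                            phase_spec.duration)
        ],
    )
    truth = GroundTruth(
        subject_id=subject_id,
        cap_type=cap_type,
        phase=phase_spec.phase,
        condition=phase_spec.condition,
        target_iapf=target,
        realized_iapf=realized if amplitude > 0 else float(realized),
        alpha_power_scale=phase_spec.alpha_power_scale,
        alpha_deficient=phase_spec.alpha_power_scale < 0.5,
        bad_channels=bad,
    )
    return rec, truth


# --------------------------------------------------------------------------
# study-level synthesis

def study_montage(cap: str) -> Montage:
    return equidistant_64() if cap == "dry" else tentwenty_64()


def plan_study(config: SynthStudyConfig) -> dict:
    """Deterministic study plan: subject offsets and alpha-deficiency.

    Subject iAPF offsets are drawn from N(0, subject_effect_sd) and then
    centered separately within the analyzed and the alpha-deficient
    cohorts, so the analyzed-cohort mean of the true per-subject iAPF
    equals the configured phase value exactly — parameter-recovery checks
    compare against the configured values without cohort sampling error.
    """
    rng = np.random.default_rng([int(config.seed) % 2**31, 901])
    n = config.n_subjects
    offsets = rng.normal(0.0, config.subject_effect_sd, n)
    deficient = rng.choice(n, size=config.n_excluded_no_alpha, replace=False)
    deficient_set = set(int(i) for i in deficient)
    retained = [i for i in range(n) if i not in deficient_set]
    if retained:
        offsets[retained] -= offsets[retained].mean()
    if deficient_set:
        idx = sorted(deficient_set)
        offsets[idx] -= offsets[idx].mean()
    deficient_phase = {
        int(i): ANALYZED_PHASES[rng.integers(len(ANALYZED_PHASES))]
        for i in sorted(deficient_set)
    }
    return {
        "subject_ids": [f"sub-{i + 1:02d}" for i in range(n)],
        "offsets": offsets,
        "deficient_phase": deficient_phase,
    }


def iter_study(config: SynthStudyConfig):
    """Yield ``(subject_id, cap, [(Recording, GroundTruth), ...])`` per
    session, generating recordings lazily (one session in memory at a
    time). Phase I is emitted as a single recording holding both the
    eyes-open and eyes-closed sub-annotations.
    """
    plan = plan_study(config)
    for si, subject_id in enumerate(plan["subject_ids"]):
        offset = float(plan["offsets"][si])
        deficient_phase = plan["deficient_phase"].get(si)
        for ci, cap in enumerate(config.cap_types):
            montage = study_montage(cap)
            specs = [
                s for s in default_phase_specs(
                    cap, phase3_duration=config.phase3_duration,
                    clean=config.clean,
                )
                if s.phase in config.phases
            ]
            session: list[tuple[Recording, GroundTruth]] = []
            phase_one: list[tuple[Recording, GroundTruth]] = []
            for pi, spec in enumerate(specs):
                if config.duration_scale != 1.0:
                    spec = replace(
                        spec, duration=spec.duration * config.duration_scale
                    )
                if deficient_phase is not None and spec.phase is deficient_phase:
                    spec = replace(
                        spec, alpha_power_scale=config.deficient_alpha_scale
                    )
                rng = np.random.default_rng(
                    [int(config.seed) % 2**31, si, ci, pi]
                )
                rec, truth = _synthesize(
                    spec, montage, offset, rng,
                    subject_id=subject_id, cap_type=cap, fs=config.fs,
                )
                if spec.phase is Phase.I:
                    phase_one.append((rec, truth))
                else:
                    session.append((rec, truth))
            if len(phase_one) == 2:
                (rec_eo, t_eo), (rec_ec, t_ec) = phase_one
                merged = Recording(
                    data=np.vstack([rec_eo.data, rec_ec.data]),
                    fs=config.fs,
                    channel_labels=rec_eo.channel_labels,
                    reference=rec_eo.reference,
                    annotations=[
                        PhaseAnnotation(Phase.I, Condition.EYES_OPEN, 0.0,
                                        rec_eo.duration),
                        PhaseAnnotation(Phase.I, Condition.EYES_CLOSED,
                                        rec_eo.duration, rec_ec.duration),
                    ],
                )
                session = [(merged, t_eo), (None, t_ec)] + session
            elif phase_one:
                session = phase_one + session
            yield subject_id, cap, session


def synthesize_study(config: SynthStudyConfig, out_dir) -> Path:
    """Write a full study tree: EDF recordings, montages, and a
    ground-truth manifest. Returns the manifest path.

    Layout::

        out/
          manifest.json
          montage_dry.tsv, montage_gel.tsv
          sub-01/dry/phase-I.edf (+ .phases.json sidecar), phase-II.edf, ...
    """
    from .edf import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cap in config.cap_types:
        save_montage(study_montage(cap), out / f"montage_{cap}.tsv")

    truths: list[dict] = []
    impedances: dict[str, dict[str, dict]] = {}
    n_written = 0
    for subject_id, cap, session in iter_study(config):
        imp_rng = np.random.default_rng(
            [int(config.seed) % 2**31, int(subject_id.split("-")[1]),
             0 if cap == "dry" else 1, 777]
        )
        impedances.setdefault(subject_id, {})[cap] = synth_impedances(
            cap, study_montage(cap), imp_rng
        )
        session_dir = out / subject_id / cap
        session_dir.mkdir(parents=True, exist_ok=True)
        for rec, truth in session:
            truths.append(truth.to_dict())
            if rec is None:  # Phase I eyes-closed shares the Phase I file
                continue
            phase = rec.annotations[0].phase
            write_edf(rec, session_dir / f"phase-{phase.value}.edf")
            n_written += 1

    manifest = {
        "config": {
            "n_subjects": config.n_subjects,
            "cap_types": list(config.cap_types),
            "subject_effect_sd": config.subject_effect_sd,
            "n_excluded_no_alpha": config.n_excluded_no_alpha,
            "seed": int(config.seed),
            "fs": config.fs,
            "phase3_duration": config.phase3_duration,
            "duration_scale": config.duration_scale,
            "clean": config.clean,
            "phases": [p.value for p in config.phases],
        },
        "true_iapf": {
            cap: {ph.value: v for ph, v in TRUE_IAPF[cap].items()}
            for cap in config.cap_types
        },
        "n_recordings": n_written,
        "recordings": truths,
        "impedances_kohm": impedances,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path


def manifest_digest(manifest_path) -> str:
    """SHA-256 of the manifest file (determinism checks)."""
    return hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()
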
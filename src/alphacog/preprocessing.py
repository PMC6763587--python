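"""Per-segment preprocessing: channel QC, bandpass, re-reference, interpolation.

The processing order per phase segment follows the analysis protocol:
bad-channel detection first (on the raw segment), then zero-phase
Butterworth bandpass, then average re-referencing excluding the bad
channels, then spherical-spline interpolation of the excluded channels.

Bad channels are classically identified by expert visual inspection; here
the three failure classes — saturated, isoelectric, predominantly
artifactual for more than 30 s — are operationalized by deterministic
window detectors with configurable thresholds, so the rule is
reproducible and can be cross-checked against injected failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import (
    DegenerateReferenceError,
    FilterError,
    InsufficientDataError,
    InterpolationRefusedError,
    ValidationError,
)
from .montage import Montage
from .recording import AVERAGE_REFERENCE, Recording

GOOD = "good"
BAD = "bad"
REASON_NONE = "none"
ISOELECTRIC = "isoelectric"
SATURATED = "saturated"
ARTIFACTUAL = "artifactual"


@dataclass
class ChannelQC:
    """Per-channel quality verdict for one phase segment."""

    labels: list[str]
    status: list[str]            # "good" | "bad"
    reason: list[str]            # "none" | failure class
    artifact_seconds: np.ndarray  # per channel, per worst failure class

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.status) == len(self.reason) == n == len(self.artifact_seconds)):
            raise ValidationError("ChannelQC field lengths disagree")
        for s, r in zip(self.status, self.reason):
            if (s == GOOD) != (r == REASON_NONE):
                raise ValidationError("reason must be 'none' iff status is 'good'")

    @property
    def good_mask(self) -> np.ndarray:
        return np.array([s == GOOD for s in self.status])

    @property
    def bad_labels(self) -> list[str]:
        return [lab for lab, s in zip(self.labels, self.status) if s == BAD]

    @property
    def n_good(self) -> int:
        return int(self.good_mask.sum())

    def to_rows(self) -> list[dict]:
        return [
            {
                "channel": lab,
                "status": s,
                "reason": r,
                "artifact_seconds": float(a),
            }
            for lab, s, r, a in zip(
                self.labels, self.status, self.reason, self.artifact_seconds
            )
        ]


@dataclass(frozen=True)
class QCThresholds:
    """Deterministic stand-ins for expert judgement of channel failures.

    A channel is bad when any single failure class accumulates more than
    ``min_bad_seconds`` (default 30 s) of 1-s windows:

    * isoelectric — window standard deviation below ``flat_sd_uv`` (µV);
    * saturated — at least ``rail_fraction`` of the window's samples
      within ``rail_band`` of the channel's observed rail (extremum),
      measured relative to the channel's peak-to-peak span;
    * artifactual — window RMS amplitude with a robust z-score (median /
      MAD over the channel's own windows) above ``artifact_z``.
    """

    window_seconds: float = 1.0
    min_bad_seconds: float = 30.0
    flat_sd_uv: float = 0.1
    rail_band: float = 0.01
    rail_fraction: float = 0.5
    artifact_z: float = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass, realized as second-order sections.

    ``order`` is the overall polynomial order of the bandpass (the design
    uses ``order // 2`` analog prototype poles); applied forward-backward,
    so the effective magnitude response is the design magnitude squared
    and the phase is zero.
    """

    order: int = 30
    band: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        if self.order % 2 != 0 or self.order <= 0:
            raise ValidationError("filter order must be a positive even number")
        if not 0 < self.band[0] < self.band[1]:
            raise ValidationError(f"invalid band {self.band}")

    def sos(self, fs: float):
        if self.band[1] >= fs / 2:
            raise ValidationError(
                f"upper cutoff {self.band[1]} Hz needs fs > {2 * self.band[1]}"
            )
        return scipy.signal.butter(
            self.order // 2, self.band, btype="bandpass", fs=fs, output="sos"
        )

    def gain(self, freqs, fs: float, *, zero_phase: bool = True) -> np.ndarray:
        """Magnitude response at ``freqs`` (squared when zero-phase)."""
        _, h = scipy.signal.sosfreqz(self.sos(fs), worN=np.atleast_1d(freqs), fs=fs)
        mag = np.abs(h)
        return mag**2 if zero_phase else mag


def detect_bad_channels(
    segment: Recording, thresholds: QCThresholds = QCThresholds()
) -> ChannelQC:
    """Flag channels failing for more than 30 s of the segment.

    Deterministic and channel-order independent: each channel is judged
    only against its own statistics.
    """
    t = thresholds
    win = int(round(t.window_seconds * segment.fs))
    n_win = segment.n_samples // win
    if n_win * t.window_seconds < t.min_bad_seconds:
        raise InsufficientDataError(
            f"QC needs at least {t.min_bad_seconds} s, got {segment.duration} s"
        )
    x = segment.data[: n_win * win]
    # (n_win, win, n_ch) view
    w = x.reshape(n_win, win, segment.n_channels)

    sd = w.std(axis=1)
    iso_win = sd < t.flat_sd_uv

    ch_max = x.max(axis=0)
    ch_min = x.min(axis=0)
    span = ch_max - ch_min
    tol = t.rail_band * np.where(span > 0, span, np.inf)
    near_rail = (w >= ch_max - tol) | (w <= ch_min + tol)
    sat_win = near_rail.mean(axis=1) >= t.rail_fraction

    rms = np.sqrt((w**2).mean(axis=1))
    med = np.median(rms, axis=0)
    mad = np.median(np.abs(rms - med), axis=0)
    scale = 1.4826 * np.where(mad > 0, mad, np.inf)
    art_win = (rms - med) / scale > t.artifact_z

    seconds = {
        ISOELECTRIC: iso_win.sum(axis=0) * t.window_seconds,
        SATURATED: sat_win.sum(axis=0) * t.window_seconds,
        ARTIFACTUAL: art_win.sum(axis=0) * t.window_seconds,
    }
    status, reason, art_secs = [], [], np.zeros(segment.n_channels)
    for ch in range(segment.n_channels):
        # reason by fixed priority among conditions over threshold: a
        # rail-pinned stretch also shows extreme amplitudes, so saturation
        # outranks the generic artifact class
        over = [key for key in (ISOELECTRIC, SATURATED, ARTIFACTUAL)
                if seconds[key][ch] > t.min_bad_seconds]
        if over:
            status.append(BAD)
            reason.append(over[0])
            art_secs[ch] = max(float(seconds[key][ch]) for key in over)
        else:
            status.append(GOOD)
            reason.append(REASON_NONE)
    return ChannelQC(list(segment.channel_labels), status, reason, art_secs)


def bandpass(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth bandpass (SOS cascade, forward-backward)."""
    if recording.fs <= 2 * spec.band[1]:
        raise ValidationError(
            f"sampling rate {recording.fs} too low for band {spec.band}"
        )
    sos = spec.sos(recording.fs)
    y = scipy.signal.sosfiltfilt(sos, recording.data, axis=0)
    if not np.all(np.isfinite(y)):
        raise FilterError("bandpass produced non-finite output")
    return recording.copy_with(data=y)


def average_reference(recording: Recording, qc: ChannelQC) -> Recording:
    """Re-reference to the mean of the good channels.

    The good-channel mean is subtracted from every channel (bad channels
    included, so their later interpolation happens in the same reference),
    making the result independent of the original physical reference.
    Idempotent; after the call the good-channel mean is zero at every
    sample to numerical precision.
    """
    mask = qc.good_mask
    if mask.sum() < 2:
        raise DegenerateReferenceError(
            f"average reference needs >= 2 good channels, have {int(mask.sum())}"
        )
    mean = recording.data[:, mask].mean(axis=1, keepdims=True)
    return recording.copy_with(
        data=recording.data - mean, reference=AVERAGE_REFERENCE
    )


# ---------------------------------------------------------------------------
# Spherical-spline interpolation (Perrin-style)

def _gm(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical spline kernel g(cos angle) = sum (2l+1)/(l(l+1))^m P_l / 4pi."""
    l = np.arange(1, n_terms + 1)
    coef = (2 * l + 1) / (l * (l + 1.0)) ** m
    shape = cosang.shape
    # evaluate all P_l via recurrence, vectorized over points
    x = cosang.ravel()
    p_prev = np.ones_like(x)
    p_cur = x.copy()
    acc = coef[0] * p_cur
    for ll in range(2, n_terms + 1):
        p_next = ((2 * ll - 1) * x * p_cur - (ll - 1) * p_prev) / ll
        acc += coef[ll - 1] * p_next
        p_prev, p_cur = p_cur, p_next
    return (acc / (4 * np.pi)).reshape(shape)


def spline_operator(
    montage: Montage,
    good_labels: list[str],
    bad_labels: list[str],
    *,
    m: int = 4,
    n_terms: int = 50,
    ridge: float = 1e-5,
) -> np.ndarray:
    """Linear operator mapping good-channel values to bad-channel estimates.

    Solves the spherical-spline system on the good electrodes (spline
    order ``m`` = 4, Legendre series truncated at ``n_terms`` = 50, ridge
    ``1e-5`` on the kernel matrix diagonal for conditioning) and evaluates
    it at the bad electrode positions. Constant fields are reproduced
    exactly regardless of the ridge, via the mean-value constraint.
    """
    gi = montage.index_of(good_labels)
    bi = montage.index_of(bad_labels)
    pg = montage.positions[gi]
    pb = montage.positions[bi]
    ng = len(gi)
    g_gg = _gm(np.clip(pg @ pg.T, -1.0, 1.0), m, n_terms) + ridge * np.eye(ng)
    g_bg = _gm(np.clip(pb @ pg.T, -1.0, 1.0), m, n_terms)
    # bordered system: [G 1; 1' 0] [c; c0] = [v; 0]
    k = np.zeros((ng + 1, ng + 1))
    k[:ng, :ng] = g_gg
    k[:ng, ng] = 1.0
    k[ng, :ng] = 1.0
    k_inv_cols = np.linalg.solve(k, np.vstack([np.eye(ng), np.zeros(ng)]))
    # estimate = c0 + G_bg @ c, linear in v
    c = k_inv_cols[:ng]          # (ng, ng): v -> c
    c0 = k_inv_cols[ng]          # (ng,):    v -> c0
    return g_bg @ c + c0[None, :]


def interpolate_bad(
    recording: Recording,
    qc: ChannelQC,
    montage: Montage,
    *,
    min_good: int = 10,
    m: int = 4,
    n_terms: int = 50,
    ridge: float = 1e-5,
) -> Recording:
    """Replace bad channels by spherical-spline estimates from good ones.

    Good channels are untouched. With fewer than ``min_good`` good
    channels the interpolation is refused (the channels stay excluded and
    the caller must handle the reduced montage).
    """
    if qc.labels != list(recording.channel_labels):
        raise ValidationError("QC labels do not match recording channels")
    bad = qc.bad_labels
    if not bad:
        return recording
    good = [lab for lab in recording.channel_labels if lab not in set(bad)]
    if len(good) < min_good:
        raise InterpolationRefusedError(
            f"only {len(good)} good channels (< {min_good}); refusing to interpolate"
        )
    op = spline_operator(montage, good, bad, m=m, n_terms=n_terms, ridge=ridge)
    gi = [recording.channel_labels.index(lab) for lab in good]
    bi = [recording.channel_labels.index(lab) for lab in bad]
    data = recording.data.copy()
    data[:, bi] = recording.data[:, gi] @ op.T
    return recording.copy_with(data=data)
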
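"""Welch spectra, whole-head mean PSD, alpha-presence gate, and the
center-of-gravity individual alpha peak frequency (iAPF).

A phase segment is divided into consecutive complete 30-s intervals; the
per-channel power spectral density is the Welch estimate averaged across
those intervals (4-s Hann windows, 50% overlap inside each interval,
density scaling: the integral of the one-sided PSD equals the signal
variance). The iAPF is the center of gravity of the whole-head mean PSD
over the alpha band (7.5-13 Hz), computed only when the alpha peak stands
at least 1.3 times above the mean of the neighboring theta (4-7.5 Hz) and
beta (13-30 Hz) band averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import ContractViolationError, InsufficientDataError, ValidationError
from .recording import Recording

ALPHA_BAND = (7.5, 13.0)
THETA_BAND = (4.0, 7.5)
BETA_BAND = (13.0, 30.0)
PRESENCE_THRESHOLD = 1.3
INTERVAL_SECONDS = 30.0


@dataclass
class SpectralResult:
    """Frequency grid plus per-channel and whole-head mean PSD (µV²/Hz)."""

    freqs: np.ndarray            # (n_freqs,)
    psd: np.ndarray              # (n_channels, n_freqs)
    channel_labels: list[str]
    n_intervals: int
    mean_psd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.psd.shape != (len(self.channel_labels), len(self.freqs)):
            raise ValidationError("psd shape does not match labels/freqs")
        if np.any(self.psd < 0):
            raise ValidationError("PSD must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")


@dataclass
class AlphaMetrics:
    """Alpha-band summary of a mean spectrum."""

    peak_power: float
    presence_ratio: float
    alpha_present: bool
    iapf: float | None = None
    alpha_band: tuple[float, float] = ALPHA_BAND


def spectral_table(result: SpectralResult):
    """Delimited-export view: frequency, per-channel PSD, whole-head mean."""
    import pandas as pd

    data = {"frequency_hz": result.freqs}
    for lab, row in zip(result.channel_labels, result.psd):
        data[lab] = row
    data["mean_psd"] = (
        result.mean_psd if result.mean_psd is not None
        else result.psd.mean(axis=0)
    )
    return pd.DataFrame(data)


def welch_psd(
    segment: Recording,
    *,
    win_seconds: float = 4.0,
    overlap: float = 0.5,
    interval_seconds: float = INTERVAL_SECONDS,
) -> SpectralResult:
    """Welch PSD averaged over consecutive complete 30-s intervals.

    Incomplete trailing intervals are dropped. Raises
    :class:`InsufficientDataError` when the segment holds no complete
    interval.
    """
    fs = segment.fs
    int_len = int(round(interval_seconds * fs))
    n_intervals = segment.n_samples // int_len
    if n_intervals == 0:
        raise InsufficientDataError(
            f"segment of {segment.duration:.1f} s holds no complete "
            f"{interval_seconds:.0f}-s interval"
        )
    nperseg = int(round(win_seconds * fs))
    noverlap = int(round(nperseg * overlap))
    # channels-first contiguous layout: much faster FFTs
    x = np.ascontiguousarray(segment.data.T)
    acc = None
    freqs = None
    for k in range(n_intervals):
        chunk = x[:, k * int_len : (k + 1) * int_len]
        freqs, p = scipy.signal.welch(
            chunk,
            fs=fs,
            window="hann",
            nperseg=nperseg,
            noverlap=noverlap,
            detrend="constant",
            scaling="density",
            axis=-1,
        )
        acc = p if acc is None else acc + p
    psd = acc / n_intervals
    return SpectralResult(
        freqs=freqs,
        psd=psd,
        channel_labels=list(segment.channel_labels),
        n_intervals=n_intervals,
    )


def mean_psd(result: SpectralResult) -> np.ndarray:
    """Unweighted whole-head mean PSD over all channels.

    Interpolated channels are expected to be present (the pipeline
    interpolates before calling Welch), so the average always runs over
    the full montage.
    """
    if result.psd.shape[0] < 1:
        raise ValidationError("mean PSD needs at least one channel")
    m = result.psd.mean(axis=0)
    result.mean_psd = m
    return m


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if freqs[0] > lo or freqs[-1] < hi:
        raise ValidationError(
            f"spectrum grid [{freqs[0]}, {freqs[-1]}] does not cover band {band}"
        )
    return (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)


def band_integral(freqs: np.ndarray, spectrum: np.ndarray,
                  band: tuple[float, float]) -> float:
    """Trapezoid integral of the spectrum over a band (edges on the grid
    get half weight; off-grid edges are linearly interpolated)."""
    lo, hi = band
    inside = (freqs > lo) & (freqs < hi)
    fgrid = [lo, *freqs[inside], hi]
    pgrid = [
        float(np.interp(lo, freqs, spectrum)),
        *spectrum[inside],
        float(np.interp(hi, freqs, spectrum)),
    ]
    return float(np.trapezoid(pgrid, fgrid))


def band_mean_power(freqs: np.ndarray, spectrum: np.ndarray,
                    band: tuple[float, float]) -> float:
    """Average power density over a band (integral / width)."""
    return band_integral(freqs, spectrum, band) / (band[1] - band[0])


def alpha_presence(
    freqs: np.ndarray,
    spectrum: np.ndarray,
    *,
    threshold: float = PRESENCE_THRESHOLD,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    theta_band: tuple[float, float] = THETA_BAND,
    beta_band: tuple[float, float] = BETA_BAND,
) -> AlphaMetrics:
    """Gate on considerable alpha activity.

    ``presence_ratio`` is the alpha-band peak of the mean PSD divided by
    the mean of the theta-band and beta-band average powers (equal weight
    per band). Alpha counts as present when the ratio reaches the
    threshold (inclusive ``>=``). A zero neighbor power yields an
    infinite ratio and a present verdict.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    peak = float(spectrum[_band_slice(freqs, alpha_band)].max())
    neighbor = 0.5 * (
        band_mean_power(freqs, spectrum, theta_band)
        + band_mean_power(freqs, spectrum, beta_band)
    )
    if neighbor <= 0:
        import warnings

        warnings.warn("zero neighboring-band power; presence ratio is infinite")
        ratio = np.inf
    else:
        ratio = peak / neighbor
    return AlphaMetrics(
        peak_power=peak,
        presence_ratio=float(ratio),
        alpha_present=bool(ratio >= threshold),
        alpha_band=alpha_band,
    )


def compute_iapf(
    freqs: np.ndarray,
    spectrum: np.ndarray,
    *,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    metrics: AlphaMetrics | None = None,
) -> float:
    """Center of gravity of the spectrum over the alpha band.

    iAPF = integral(f * P(f)) / integral(P(f)) over [7.5, 13] Hz, with
    trapezoid weights (band edges get half weight on a grid that hits
    them exactly). The result always lies inside the band. Calling this
    when the presence gate failed is a contract violation.
    """
    if metrics is not None and not metrics.alpha_present:
        raise ContractViolationError(
            "compute_iapf called although the alpha-presence gate failed"
        )
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if np.any(spectrum < 0):
        raise ValidationError("spectrum must be nonnegative")
    den = band_integral(freqs, spectrum, alpha_band)
    if den <= 0:
        raise ValidationError("zero alpha-band power: center of gravity undefined")
    num = band_integral(freqs, freqs * spectrum, alpha_band)
    return num / den


def analyze_mean_spectrum(
    freqs: np.ndarray, spectrum: np.ndarray, *, threshold: float = PRESENCE_THRESHOLD
) -> AlphaMetrics:
    """Presence gate plus iAPF (iAPF set only when alpha is present)."""
    metrics = alpha_presence(freqs, spectrum, threshold=threshold)
    if metrics.alpha_present:
        metrics.iapf = compute_iapf(freqs, spectrum, metrics=metrics)
    return metrics
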
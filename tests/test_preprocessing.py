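"""Bad-channel detection, zero-phase bandpass, average reference, and
spherical-spline interpolation."""

import numpy as np
import pytest

from alphacog.errors import (
    DegenerateReferenceError,
    InsufficientDataError,
    InterpolationRefusedError,
    ValidationError,
)
from alphacog.phases import Condition, Phase
from alphacog.preprocessing import (
    ARTIFACTUAL,
    BAD,
    GOOD,
    ISOELECTRIC,
    SATURATED,
    ChannelQC,
    FilterSpec,
    average_reference,
    bandpass,
    detect_bad_channels,
    interpolate_bad,
    spline_operator,
)
from alphacog.recording import Recording
from alphacog.synth import SynthPhaseSpec, synthesize_recording


def _rec(data, fs=128):
    return Recording(np.asarray(data, float), fs,
                     [f"ch{i}" for i in range(data.shape[1])])


def _noise(n_sec, n_ch, fs=128, seed=0, std=10.0):
    return np.random.default_rng(seed).normal(0, std, (int(n_sec * fs), n_ch))


class TestDetectBadChannels:
    def test_constant_channel_is_isoelectric(self):
        data = _noise(120, 3)
        data[:, 1] = 7.5
        qc = detect_bad_channels(_rec(data))
        assert qc.status == [GOOD, BAD, GOOD]
        assert qc.reason[1] == ISOELECTRIC

    def test_rail_clipped_channel_is_saturated(self):
        data = _noise(120, 3)
        fs = 128
        data[: 40 * fs, 2] = 400.0 - np.abs(_noise(40, 1, seed=1, std=0.5))[:, 0]
        qc = detect_bad_channels(_rec(data, fs))
        assert qc.status[2] == BAD
        assert qc.reason[2] == SATURATED

    def test_high_amplitude_burst_is_artifactual(self):
        data = _noise(120, 3)
        fs = 128
        data[: 40 * fs, 0] += _noise(40, 1, seed=2, std=100.0)[:, 0]
        qc = detect_bad_channels(_rec(data, fs))
        assert qc.reason[0] == ARTIFACTUAL
        assert qc.artifact_seconds[0] >= 30

    def test_short_failures_stay_good(self):
        """Failures must persist for more than 30 s to count."""
        data = _noise(120, 2)
        fs = 128
        data[: 20 * fs, 0] = 0.0  # 20 s flat: under the threshold
        qc = detect_bad_channels(_rec(data, fs))
        assert qc.status == [GOOD, GOOD]

    def test_segment_under_30s_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_bad_channels(_rec(_noise(20, 2)))

    def test_order_independent(self):
        data = _noise(60, 4)
        data[:, 2] = 1.0
        rec = _rec(data)
        qc = detect_bad_channels(rec)
        perm = [3, 2, 0, 1]
        rec_p = Recording(data[:, perm], 128, [f"ch{i}" for i in perm])
        qc_p = detect_bad_channels(rec_p)
        verdict = dict(zip(qc.labels, qc.status))
        verdict_p = dict(zip(qc_p.labels, qc_p.status))
        assert verdict == verdict_p

    def test_qc_invariant_reason_iff_bad(self):
        with pytest.raises(ValidationError):
            ChannelQC(["a"], [GOOD], [ISOELECTRIC], np.zeros(1))


def tone_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Amplitude of the ``freq`` component by quadrature projection over an
    integer number of cycles (robust to slowly decaying filter transients
    from the sharp 1 Hz edge)."""
    n_cycles = int(freq * len(x) / fs)
    n = int(round(n_cycles * fs / freq))
    t = np.arange(n) / fs
    c = x[:n] @ np.cos(2 * np.pi * freq * t) * 2 / n
    s = x[:n] @ np.sin(2 * np.pi * freq * t) * 2 / n
    return float(np.hypot(c, s))


class TestBandpass:
    FS = 1024

    def test_dc_is_removed(self):
        rec = _rec(np.full((self.FS * 4, 2), 50.0), fs=self.FS)
        out = bandpass(rec)
        assert np.abs(out.data[self.FS : -self.FS]).max() < 50e-3

    @pytest.mark.parametrize("freq,tol", [(5, 0.01), (10, 0.01), (20, 0.01)])
    def test_passband_tone_gain_matches_transfer_oracle(self, freq, tol):
        t = np.arange(self.FS * 40) / self.FS
        rec = _rec(np.sin(2 * np.pi * freq * t)[:, None], fs=self.FS)
        out = bandpass(rec)
        mid = out.data[10 * self.FS : -10 * self.FS, 0]
        measured = tone_amplitude(mid, self.FS, freq)
        oracle = FilterSpec().gain(freq, self.FS)[0]  # |H|^2 (zero phase)
        assert measured == pytest.approx(oracle, rel=tol)

    def test_stopband_100hz_attenuation(self):
        t = np.arange(self.FS * 40) / self.FS
        rec = _rec(np.sin(2 * np.pi * 100 * t)[:, None], fs=self.FS)
        out = bandpass(rec)
        mid = out.data[10 * self.FS : -10 * self.FS, 0]
        assert 20 * np.log10(tone_amplitude(mid, self.FS, 100.0)) < -60

    def test_design_minus3db_at_cutoffs(self):
        gains = FilterSpec().gain(np.array([1.0, 40.0]), self.FS,
                                  zero_phase=False)
        np.testing.assert_allclose(gains, 1 / np.sqrt(2), rtol=1e-6)

    def test_low_rate_refused(self):
        with pytest.raises(ValidationError):
            bandpass(_rec(np.zeros((300, 1)), fs=60))

    def test_filter_and_reference_commute(self):
        data = _noise(10, 4, fs=256, seed=3)
        rec = _rec(data, fs=256)
        qc = detect_bad_channels(_rec(_noise(60, 4, fs=256, seed=3), fs=256))
        a = average_reference(bandpass(rec), qc)
        b = bandpass(average_reference(rec, qc))
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)


class TestAverageReference:
    def _qc(self, n, bad=()):
        status = [BAD if i in bad else GOOD for i in range(n)]
        reason = [ISOELECTRIC if i in bad else "none" for i in range(n)]
        return ChannelQC([f"ch{i}" for i in range(n)], status, reason,
                         np.zeros(n))

    def test_good_channel_mean_is_zero_everywhere(self):
        rec = _rec(_noise(5, 6, seed=1))
        out = average_reference(rec, self._qc(6, bad=(2,)))
        good = [i for i in range(6) if i != 2]
        assert np.abs(out.data[:, good].mean(axis=1)).max() <= 1e-10

    def test_bad_channel_offset_does_not_leak(self):
        data = _noise(5, 4, seed=2)
        ref = average_reference(_rec(data), self._qc(4, bad=(0,)))
        data2 = data.copy()
        data2[:, 0] += 1e6  # huge offset on the excluded channel
        ref2 = average_reference(_rec(data2), self._qc(4, bad=(0,)))
        np.testing.assert_allclose(ref.data[:, 1:], ref2.data[:, 1:],
                                   atol=1e-9)

    def test_idempotent(self):
        rec = _rec(_noise(5, 5, seed=4))
        qc = self._qc(5)
        once = average_reference(rec, qc)
        twice = average_reference(once, qc)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_fewer_than_two_good_channels_refused(self):
        rec = _rec(_noise(5, 3, seed=5))
        with pytest.raises(DegenerateReferenceError):
            average_reference(rec, self._qc(3, bad=(0, 1)))


class TestSphericalSpline:
    def test_constant_field_reproduced_exactly(self, eq_montage):
        op = spline_operator(eq_montage, eq_montage.labels[:50],
                             eq_montage.labels[50:])
        np.testing.assert_allclose(op @ np.full(50, 3.7), 3.7, atol=1e-6)

    @pytest.mark.parametrize("fixture", ["eq_montage", "tt_montage"])
    def test_leave_one_out_on_smooth_field(self, fixture, request):
        """<= 5 % error on a low-order spherical-harmonic field, for every
        electrode inside the cap hull (the below-rim mastoids of the 10-20
        layout are extrapolation targets and are excluded)."""
        mont = request.getfixturevalue(fixture)
        pts = mont.positions
        field = (1.5 + pts[:, 2] + 0.8 * pts[:, 0] * pts[:, 1]
                 + 0.5 * (2.5 * pts[:, 2] ** 3 - 1.5 * pts[:, 2]))
        scale = np.abs(field).max()
        for i, label in enumerate(mont.labels):
            if pts[i, 2] < -0.2:  # below the cap rim: extrapolation
                continue
            good = [lab for j, lab in enumerate(mont.labels) if j != i]
            vals = np.delete(field, i)
            est = spline_operator(mont, good, [label]) @ vals
            assert abs(est[0] - field[i]) / scale <= 0.05, label

    def test_good_channels_untouched_and_bad_replaced(self, eq_montage):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 10, (256, 64))
        rec = Recording(data, 128, list(eq_montage.labels))
        status = [GOOD] * 64
        reason = ["none"] * 64
        status[5], reason[5] = BAD, ISOELECTRIC
        qc = ChannelQC(list(eq_montage.labels), status, reason, np.zeros(64))
        out = interpolate_bad(rec, qc, eq_montage)
        good_idx = [i for i in range(64) if i != 5]
        np.testing.assert_array_equal(out.data[:, good_idx],
                                      data[:, good_idx])
        assert not np.array_equal(out.data[:, 5], data[:, 5])
        assert np.all(np.isfinite(out.data))

    def test_no_bad_channels_is_identity(self, eq_montage):
        data = np.random.default_rng(9).normal(0, 1, (64, 64))
        rec = Recording(data, 128, list(eq_montage.labels))
        qc = ChannelQC(list(eq_montage.labels), [GOOD] * 64, ["none"] * 64,
                       np.zeros(64))
        assert interpolate_bad(rec, qc, eq_montage) is rec

    def test_too_few_good_channels_refused(self, eq_montage):
        data = np.zeros((64, 64))
        rec = Recording(data, 128, list(eq_montage.labels))
        status = [BAD] * 60 + [GOOD] * 4
        reason = [ISOELECTRIC] * 60 + ["none"] * 4
        qc = ChannelQC(list(eq_montage.labels), status, reason, np.zeros(64))
        with pytest.raises(InterpolationRefusedError):
            interpolate_bad(rec, qc, eq_montage)


class TestEndToEndQCCrossCheck:
    def test_injected_failures_are_detected_with_correct_class(self, eq_montage):
        spec = SynthPhaseSpec(Phase.III, Condition.EYES_OPEN, 120.0, 10.3,
                              bad_channel_rate=0.25, artifact_burst_rate=0.0)
        rec, truth = synthesize_recording(spec, eq_montage, seed=13, fs=128)
        qc = detect_bad_channels(rec)
        detected = dict(zip(qc.labels, qc.reason))
        for label, kind in truth.bad_channels.items():
            assert detected[label] == kind, label
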
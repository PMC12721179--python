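"""Smoothing, speed, bout detection, strides, and limb phase."""

import numpy as np
import pandas as pd
import pytest

from gaitcode.kinematics import (
    WalkBout,
    bandpass_gait,
    body_speed,
    detect_bouts,
    limb_phase,
    segment_strides,
    smooth_positions,
)
from gaitcode.session import KINEMATICS_COLUMNS, ValidationError

FR = 80.0


def _kin_from_channels(**channels):
    n = len(next(iter(channels.values())))
    data = {c: np.zeros(n) for c in KINEMATICS_COLUMNS}
    data["frame"] = np.arange(n)
    data.update(channels)
    return pd.DataFrame(data)[KINEMATICS_COLUMNS]


class TestSmoothing:
    def test_cubic_polynomial_reproduced(self):
        t = np.arange(400, dtype=float)
        poly = 1e-4 * t**3 - 0.02 * t**2 + 0.5 * t - 3
        out = smooth_positions(_kin_from_channels(nose_x=poly))
        assert np.allclose(out["nose_x"], poly, atol=1e-9)

    def test_noise_variance_reduced(self):
        # a 15-frame cubic window attenuates white-noise sd by >= 2x
        # (the 7-frame default trades some of that for 8 Hz fidelity)
        rng = np.random.default_rng(0)
        t = np.arange(2000, dtype=float)
        noisy = 0.1 * t + rng.normal(0, 0.5, t.size)
        out = smooth_positions(_kin_from_channels(lf_x=noisy), window_frames=15)
        resid = out["lf_x"] - 0.1 * t
        assert resid.std() <= 0.5 / 2

    def test_constant_unchanged(self):
        out = smooth_positions(_kin_from_channels(rr_y=np.full(100, 7.0)))
        assert np.allclose(out["rr_y"], 7.0, atol=1e-12)

    def test_window_too_short(self):
        with pytest.raises(ValueError, match="window"):
            smooth_positions(_kin_from_channels(nose_x=np.zeros(50)), window_frames=4)


class TestBodySpeed:
    def test_equal_limb_speeds(self):
        t = np.arange(100) / FR
        kin = _kin_from_channels(
            **{f"{l}_x": 100.0 * t for l in ("lf", "rf", "lr", "rr")}
        )
        assert np.allclose(body_speed(kin, FR), 100.0)

    def test_rms_of_mixed_speeds(self):
        t = np.arange(100) / FR
        kin = _kin_from_channels(lr_x=100.0 * t, rr_x=100.0 * t)
        assert np.allclose(body_speed(kin, FR), np.sqrt(2 * 100.0**2 / 4))

    def test_stationary_is_zero(self):
        assert np.allclose(body_speed(_kin_from_channels(nose_x=np.zeros(50)), FR), 0.0)


def _speed_trace(peak, plateau_s=2.0, rise_s=0.2, total_s=10.0, start_s=4.0):
    """Raised-cosine rise to `peak` mm/s; peak acceleration = peak*pi/(2*rise)."""
    n = int(total_s * FR)
    v = np.zeros(n)
    a = int(start_s * FR)
    r = int(rise_s * FR)
    p = int(plateau_s * FR)
    v[a : a + r] = peak * 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
    v[a + r : a + r + p] = peak
    v[a + r + p : a + 2 * r + p] = peak * 0.5 * (
        1 + np.cos(np.pi * np.arange(r) / r)
    )
    return v


class TestBoutDetection:
    def test_single_bout_onset_at_accel_peak(self):
        v = _speed_trace(peak=255.0)  # peak accel ~2000 mm/s^2
        bouts = detect_bouts(v, FR)
        assert len(bouts) == 1
        accel = np.gradient(v) * FR
        assert abs(bouts[0].onset_frame - np.argmax(accel)) <= 1
        assert bouts[0].peak_prominence > 1000.0

    def test_low_prominence_rejected(self):
        v = _speed_trace(peak=110.0)  # peak accel ~860 mm/s^2
        assert detect_bouts(v, FR) == []

    def test_short_bout_rejected(self):
        v = _speed_trace(peak=255.0, plateau_s=0.45, rise_s=0.1)  # ~0.8 s above
        assert detect_bouts(v, FR) == []

    def test_close_pair_keeps_earlier(self):
        # two bouts separated by a 0.6 s rest: the later one is dropped
        v1 = _speed_trace(peak=255.0, plateau_s=1.2, total_s=8.0, start_s=2.0)
        v2 = _speed_trace(peak=255.0, plateau_s=1.5, total_s=8.0, start_s=4.2)
        v = np.maximum(v1, v2)
        bouts = detect_bouts(v, FR)
        assert len(bouts) == 1
        assert bouts[0].onset_frame < 4.2 * FR

    def test_well_separated_pair_both_kept(self):
        v1 = _speed_trace(peak=255.0, plateau_s=1.2, total_s=12.0, start_s=2.0)
        v2 = _speed_trace(peak=255.0, plateau_s=1.5, total_s=12.0, start_s=7.0)
        assert len(detect_bouts(np.maximum(v1, v2), FR)) == 2


class TestBandpass:
    def test_gait_frequency_preserved(self):
        t = np.arange(4000) / FR
        sig = np.sin(2 * np.pi * 2.5 * t)
        out = bandpass_gait(sig, FR)
        core = slice(400, -400)
        assert np.abs(out[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_removed(self):
        t = np.arange(8000) / FR
        drift = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass_gait(drift + np.sin(2 * np.pi * 2.5 * t), FR)
        resid = out - bandpass_gait(np.sin(2 * np.pi * 2.5 * t), FR)
        assert np.abs(resid).max() < 0.1  # >= 20 dB down

    def test_constant_zeroed(self):
        out = bandpass_gait(np.full(1000, 5.0), FR)
        assert np.abs(out).max() < 1e-6

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="filter lengths"):
            bandpass_gait(np.zeros(30), FR)


class TestStrides:
    def test_pure_sine_stride_count_and_interval(self):
        t = np.arange(480) / FR  # 6 s signal, 4 s bout inside
        sig = np.sin(2 * np.pi * 2.5 * t)
        bout = WalkBout(80, 400, 2000.0)
        strides = segment_strides(sig, bout, "lf", FR)
        stance = [s.stance_onset_frame for s in strides]
        assert 7 <= len(stance) + 1 <= 10  # 9 +/- 1 onsets -> 8 +/- 1 strides
        intervals = np.diff(stance)
        assert np.all(np.abs(intervals - 0.4 * FR) <= 1)

    def test_monotone_signal_empty(self):
        bout = WalkBout(0, 200, 2000.0)
        assert segment_strides(np.linspace(0, 1, 200), bout, "lf", FR) == []

    def test_swing_onset_between_stances(self, trot_seg):
        for limb, strides in trot_seg.strides.items():
            for s in strides:
                assert s.stance_onset_frame < s.swing_onset_frame < s.end_frame


class TestLimbPhase:
    def test_sinusoid_phase_linear(self):
        t = np.arange(4000) / FR
        sig = -np.cos(2 * np.pi * 2.5 * t)  # minima at t = 0, 0.4, ...
        ps = limb_phase(sig, [WalkBout(400, 3600, 2000.0)], "lf")
        core = ps.phase_deg[400:3600]
        expected = (np.degrees(2 * np.pi * 2.5 * t[400:3600]) ) % 360.0
        d = (core - expected + 180) % 360 - 180
        assert np.nanmax(np.abs(d)) < 2.0

    def test_phase_masked_outside_bouts(self):
        t = np.arange(1000) / FR
        ps = limb_phase(np.sin(2 * np.pi * 2.5 * t), [WalkBout(100, 300, 2000.0)], "lf")
        assert np.all(np.isnan(ps.phase_deg[:100]))
        assert np.all(np.isfinite(ps.phase_deg[100:300]))

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValidationError, match="undefined"):
            limb_phase(np.zeros(1000), [WalkBout(0, 500, 2000.0)], "lf")

    def test_sign_flip_shifts_by_180(self):
        t = np.arange(4000) / FR
        sig = np.sin(2 * np.pi * 2.5 * t)
        bouts = [WalkBout(400, 3600, 2000.0)]
        a = limb_phase(sig, bouts, "lf").phase_deg[500:3500]
        b = limb_phase(-sig, bouts, "lf").phase_deg[500:3500]
        d = (a - b) % 360.0
        assert np.allclose(np.abs(d - 180.0), 0.0, atol=2.0)


class TestEndToEndRecovery:
    def test_bout_recovery(self, trot_kin, trot_seg):
        _, truth = trot_kin
        detected = np.array([b.onset_frame for b in trot_seg.bouts])
        gt = truth.bouts["onset_frame"].to_numpy()
        errs = np.array([np.min(np.abs(detected - g)) for g in gt])
        assert np.mean(errs <= 25) >= 0.9
        assert np.median(errs) <= 3

    def test_stance_onset_recovery(self, trot_kin, trot_seg):
        _, truth = trot_kin
        for limb in ("lf", "rr"):
            det = np.array([s.stance_onset_frame for s in trot_seg.strides[limb]])
            gt = truth.stance_onsets[limb]
            errs = np.array([np.min(np.abs(gt - d)) for d in det])
            assert np.mean(errs <= 2) >= 0.95

    def test_phase_zero_at_detected_stance_onsets(self, trot_seg):
        ps = trot_seg.phases["lf"]
        frames = [
            s.stance_onset_frame
            for s in trot_seg.strides["lf"]
            if np.isfinite(ps.phase_deg[s.stance_onset_frame])
        ]
        ph = np.radians(ps.phase_deg[frames])
        mean = np.degrees(np.angle(np.mean(np.exp(1j * ph))))
        assert abs(mean) < 10.0

    def test_phase_covers_all_bins_within_stride(self, trot_seg):
        ps = trot_seg.phases["rf"]
        covered = 0
        strides = trot_seg.strides["rf"][:50]
        for s in strides:
            ph = ps.phase_deg[s.stance_onset_frame : s.end_frame]
            bins = np.unique((ph[np.isfinite(ph)] // 30).astype(int))
            covered += len(bins) == 12
        assert covered >= 0.9 * len(strides)
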
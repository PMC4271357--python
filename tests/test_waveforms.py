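import numpy as np
import pytest

from aortasv.params import MMHG_CGS
from aortasv.simulator import true_stroke_volume
from aortasv.waveforms import (PressureWaveform, detect_foot, extract_features,
                               foot_times, mid_aortic_area,
                               pulse_wave_velocity, pwv_between, segment_beats)
from conftest import synthetic_pulse


class TestPressureWaveform:
    def test_rejects_nonuniform_sampling(self):
        with pytest.raises(ValueError, match="uniform"):
            PressureWaveform(np.array([0.0, 1.0, 2.5]), np.zeros(3))

    def test_rejects_short_or_nonfinite(self):
        with pytest.raises(ValueError):
            PressureWaveform(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            PressureWaveform(np.array([0.0, 1.0]), np.array([1.0, np.nan]))


class TestSegmentBeats:
    def test_sawtooth_onsets_at_minima(self):
        t = np.arange(0, 3.0, 1e-3)
        v = (t % 0.75) * 40  # rising sawtooth, period 0.75
        beats = segment_beats(PressureWaveform(t, v), 0.75)
        # interior minima at 0.75, 1.5, 2.25 bound two complete beats
        assert [t[b[0]] for b in beats] == pytest.approx([0.75, 1.5], abs=2e-3)
        assert t[beats[-1][1]] == pytest.approx(2.25, abs=2e-3)

    def test_constant_signal_is_degenerate(self):
        t = np.arange(0, 1.0, 1e-3)
        with pytest.raises(ValueError, match="constant"):
            segment_beats(PressureWaveform(t, np.full_like(t, 7.0)), 0.75)

    def test_simulated_window_has_expected_beat_count(self, normal_record):
        # 1.5 s window at HR 80: two diastolic onsets -> one complete beat
        beats = segment_beats(normal_record.channel("p_a5"), 0.75)
        assert len(beats) == 1


class TestDetectFoot:
    def test_linear_upstroke_closed_form(self):
        # 80 -> 120 mmHg over 0.1 s: threshold 80.8 crossed at t = 0.002
        t = np.arange(0.0, 0.1 + 1e-9, 1e-3)
        v = 80.0 + 400.0 * t
        w = PressureWaveform(t, v)
        foot = detect_foot(w, (0, len(t) - 1), dbp=80.0, pp=40.0)
        assert foot == pytest.approx(0.002, abs=1e-9)

    def test_translation_equivariance(self):
        t = np.arange(0.0, 0.1 + 1e-9, 1e-3)
        v = 80.0 + 400.0 * t
        w0 = PressureWaveform(t, v)
        w1 = PressureWaveform(t + 0.045, v)
        beat = (0, len(t) - 1)
        assert (detect_foot(w1, beat, 80.0, 40.0)
                == pytest.approx(detect_foot(w0, beat, 80.0, 40.0) + 0.045))

    def test_no_crossing_errors(self):
        t = np.arange(0.0, 0.1, 1e-3)
        w = PressureWaveform(t, np.full_like(t, 80.0))
        with pytest.raises(ValueError, match="crossing"):
            detect_foot(w, (0, len(t) - 1), dbp=80.0, pp=40.0)

    def test_distal_foot_later_than_proximal(self, normal_record):
        f2 = foot_times(normal_record.channel("p_a2"), 0.75)
        f8 = foot_times(normal_record.channel("p_a8"), 0.75)
        assert min(f8) > min(f2)

    def test_foot_times_increase_down_the_aorta(self, normal_record):
        feet = [min(foot_times(normal_record.channel(f"p_a{m}"), 0.75))
                for m in range(2, 9)]
        assert all(a < b for a, b in zip(feet, feet[1:]))


class TestExtractFeatures:
    def test_piecewise_linear_pulse(self):
        t, v = synthetic_pulse(n_beats=3)
        w = PressureWaveform(t, v)
        beats = segment_beats(w, 0.75)
        f = extract_features(w, beats[0])
        assert f.sbp == pytest.approx(120.0, abs=0.5)
        assert f.dbp == pytest.approx(80.0, abs=0.5)
        assert f.pp == pytest.approx(40.0, abs=1.0)
        assert f.ph == pytest.approx(100.0, abs=0.5)
        assert f.t_p == pytest.approx(0.12, abs=2e-3)
        assert f.t_h == pytest.approx(0.33, abs=2e-3)
        assert f.period == pytest.approx(0.75, abs=2e-3)

    def test_backward_scan_takes_last_half_crossing(self):
        """Post-peak oscillation crossing the half level three times downward."""
        period, fs = 1.0, 1000.0
        # one beat: upstroke to 100, decay with two bounces around the
        # half level (50), back to 0 at the next onset
        knots_t = [0.0, 0.1, 0.3, 0.35, 0.45, 0.5, 1.0]
        knots_v = [0.0, 100.0, 40.0, 60.0, 30.0, 55.0, 0.0]
        t = np.arange(0.0, 3 * period, 1.0 / fs)
        v = np.interp(t % period, knots_t, knots_v)
        w = PressureWaveform(t, v)
        beats = segment_beats(w, period)
        # the mid-decay valley at 30 can also register as a minimum; take
        # the beat anchored at the true (zero-level) onset
        beat = min(beats, key=lambda b: v[b[0]])
        f = extract_features(w, beat)
        half = f.ph
        assert half == pytest.approx(50.0, abs=0.5)
        i0, i1 = beat
        seg = v[i0:i1]
        down = np.where((seg[:-1] >= half) & (seg[1:] < half))[0]
        assert len(down) >= 3  # oscillation really does re-cross
        # brute force over all crossings: the last one, interpolated
        i = down[-1]
        frac = (seg[i] - half) / (seg[i] - seg[i + 1])
        expect = (i + frac) / fs
        assert f.t_h == pytest.approx(expect, abs=1e-9)
        # the constructed final crossing sits on the 55 -> 0 ramp
        assert f.t_h == pytest.approx(0.5 + (55 - 50) / 55 * 0.5, abs=2e-3)

    def test_amplitude_scaling_equivariance(self):
        t, v = synthetic_pulse()
        w1 = PressureWaveform(t, v)
        w2 = PressureWaveform(t, 2.0 * v)
        b1 = segment_beats(w1, 0.75)[0]
        b2 = segment_beats(w2, 0.75)[0]
        f1, f2 = extract_features(w1, b1), extract_features(w2, b2)
        assert f2.sbp == pytest.approx(2 * f1.sbp)
        assert f2.pp == pytest.approx(2 * f1.pp)
        assert f2.t_p == pytest.approx(f1.t_p)
        assert f2.t_h == pytest.approx(f1.t_h)

    def test_degenerate_flat_beat(self):
        t = np.arange(0.0, 1.0, 1e-3)
        w = PressureWaveform(t, np.concatenate([[79.9], np.full(len(t) - 1, 80.0)]))
        with pytest.raises(ValueError):
            extract_features(w, (0, len(t) - 1))

    def test_radius_and_pressure_halftime_agree_in_linear_mode(self, normal_record):
        wp = normal_record.channel("p_a5")
        wr = normal_record.channel("r_a5")
        fp = extract_features(wp, segment_beats(wp, 0.75)[0])
        fr = extract_features(wr, segment_beats(wr, 0.75)[0])
        # linear compliance: radius is a monotone static map of pressure,
        # so times agree closely; the sqrt(V) map's concavity shifts the
        # radius half level slightly, hence a few-ms tolerance on t_h
        assert fr.t_h == pytest.approx(fp.t_h, abs=0.010)
        assert fr.t_p == pytest.approx(fp.t_p, abs=5e-3)


class TestPulseWaveVelocity:
    def test_constructed_lag(self):
        t, v = synthetic_pulse(n_beats=4)
        w1 = PressureWaveform(t, v)
        lag = 45  # samples of 1 ms
        w2 = PressureWaveform(t, np.roll(v, lag))
        assert pwv_between(w1, w2, 30.0, 0.75) == pytest.approx(30.0 / 0.045,
                                                                rel=1e-3)

    def test_normal_run_near_printed_value(self, normal_record):
        assert pulse_wave_velocity(normal_record) == pytest.approx(667.0, rel=0.05)

    def test_bramwell_hill_consistency(self, normal_record):
        """Measured PWV matches sqrt(V_seg·1333.22/(rho·C_seg)) within 10%."""
        v_meas = pulse_wave_velocity(normal_record)
        w = normal_record.channel("r_a5")
        onset = segment_beats(w, 0.75)[0][0]
        v_dia = np.pi * w.values[onset] ** 2 * 5.0
        v_bh = np.sqrt(v_dia * MMHG_CGS / (1.03 * 0.13))
        assert v_meas == pytest.approx(v_bh, rel=0.10)


class TestMidAorticArea:
    def test_constant_radius(self):
        # build a fake record with constant 1.5 cm radii and a pulsatile marker
        from aortasv.simulator import SimulationRecord

        t = np.arange(0.0, 1.5, 1e-3)
        pulse = 100.0 + 20.0 * np.sin(2 * np.pi * t / 0.75)
        rec = SimulationRecord(
            sample_times=t,
            seg_pressure_series=np.tile(pulse[:, None], (1, 10)),
            seg_radius_series=np.full((len(t), 10), 1.5)
            + 1e-4 * np.sin(2 * np.pi * t / 0.75)[:, None],
            pump_outflow_series=np.zeros_like(t),
            pump_pressure_series=pulse,
            venous_pressure_series=np.zeros_like(t),
            params=None,
        )
        rec.params = type("P", (), {"period": 0.75})()
        assert mid_aortic_area(rec) == pytest.approx(np.pi * 1.5**2, rel=1e-3)

    def test_normal_run_diastolic_area(self, normal_record):
        # diastolic volume ~ 35.34 + 0.13*(DBP-10) ml over a 5 cm segment
        a = mid_aortic_area(normal_record)
        assert a == pytest.approx(8.9, rel=0.05)

    def test_scales_with_radius_squared(self, normal_record):
        import dataclasses

        scaled = dataclasses.replace(
            normal_record, seg_radius_series=2.0 * normal_record.seg_radius_series)
        assert mid_aortic_area(scaled) == pytest.approx(
            4.0 * mid_aortic_area(normal_record), rel=1e-9)

    def test_true_sv_roughly_compliance_times_pp(self, normal_record):
        # clinical rule of thumb: SV in ml about 1.5x pulse pressure in mmHg,
        # here with total compliance 1.3 ml/mmHg expect SV >= C*PP/2
        w = normal_record.channel("p_a5")
        f = extract_features(w, segment_beats(w, 0.75)[0])
        sv = true_stroke_volume(normal_record)
        assert 0.5 * 1.3 * f.pp < sv < 2.5 * 1.3 * f.pp
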
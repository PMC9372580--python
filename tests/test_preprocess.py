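"""Signal-conditioning checks: filter responses, RMS envelope, baseline
removal, artifact flagging and MVC reference extraction against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skiemg.containers import ConfigurationError, MvcTrial, MvcTrialSet
from skiemg.preprocess import (
    ACCR_CUTOFF_HZ,
    ANGLE_CUTOFF_HZ,
    angular_velocity,
    artifact_mask,
    bandpass_emg,
    lowpass_accr,
    lowpass_angles,
    mvc_reference,
    normalize_to_mvc,
    remove_baseline,
    rms_envelope,
)
from skiemg.synth import SynthConfig, generate_mvc_trials, generate_session

FS_EMG = 1926.0
FS_MOT = 148.0


def sine(freq, fs, dur, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


def interior(x, frac=0.2):
    n = len(x)
    k = int(n * frac)
    return x[k : n - k]


class TestBandpassEmg:
    def test_dc_rejected(self):
        x = np.full(4000, 3.7)
        out = bandpass_emg(x, FS_EMG)
        assert np.max(np.abs(out)) < 1e-6 * 3.7

    def test_passband_tone_preserved(self):
        x, _ = sine(100.0, FS_EMG, 4.0)
        out = interior(bandpass_emg(x, FS_EMG))
        assert np.max(np.abs(out)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        x, _ = sine(5.0, FS_EMG, 4.0)
        out = interior(bandpass_emg(x, FS_EMG))
        assert np.max(np.abs(out)) < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass_emg(np.zeros(1000), 900.0)  # 500 Hz edge >= 450 Hz Nyquist


class TestRmsEnvelope:
    def test_constant_passthrough(self):
        out = rms_envelope(np.full(2000, 2.5), FS_EMG)
        assert np.allclose(out, 2.5)

    def test_unit_sine_is_inverse_sqrt2(self):
        x, _ = sine(100.0, FS_EMG, 2.0)
        env = interior(rms_envelope(x, FS_EMG))
        assert np.allclose(env, 1 / np.sqrt(2), rtol=0.01)

    def test_zeros(self):
        assert np.allclose(rms_envelope(np.zeros(1000), FS_EMG), 0.0)

    def test_epoch_validation(self):
        with pytest.raises(ConfigurationError):
            rms_envelope(np.ones(100), FS_EMG, epoch_ms=0)
        with pytest.raises(ConfigurationError):
            rms_envelope(np.ones(10), FS_EMG, epoch_ms=125)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_sign_invariant(self, seed):
        x = np.random.default_rng(seed).standard_normal(600)
        e1 = rms_envelope(x, FS_EMG)
        e2 = rms_envelope(-x, FS_EMG)
        assert np.all(e1 >= 0)
        assert np.allclose(e1, e2)


class TestRemoveBaseline:
    def test_linear_ramp_vanishes_interior(self):
        x = np.linspace(0, 5, int(4 * FS_EMG))
        out = remove_baseline(x, FS_EMG)
        assert np.max(np.abs(interior(out, 0.3))) < 1e-9

    def test_drift_removed_tone_preserved(self):
        _, t = sine(50.0, FS_EMG, 10.0)
        tone = np.sin(2 * np.pi * 50.0 * t)
        drift = 2.0 * np.sin(2 * np.pi * 0.2 * t)
        out = interior(remove_baseline(tone + drift, FS_EMG))
        # residual drift: correlate against the drift waveform
        d = interior(drift)
        drift_amp = 2 * np.dot(out, d) / np.dot(d, d)
        assert abs(drift_amp) < 0.2 * 2.0  # >80% of the drift removed
        tone_ref = interior(tone)
        tone_amp = np.dot(out, tone_ref) / np.dot(tone_ref, tone_ref)
        assert tone_amp == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        assert np.allclose(remove_baseline(np.zeros(3000), FS_EMG), 0.0)

    def test_too_short_errors(self):
        with pytest.raises(ConfigurationError):
            remove_baseline(np.zeros(100), FS_EMG)


class TestArtifactMask:
    def test_spike_flagged(self):
        rng = np.random.default_rng(0)
        env = np.abs(1.0 + 0.1 * rng.standard_normal(5000))
        rep0 = artifact_mask(env)
        env[2500] = rep0.mean + 10 * rep0.sd
        rep = artifact_mask(env)
        assert rep.mask[2500]
        assert any(a <= 2500 < b for a, b in rep.intervals)

    def test_constant_envelope_no_flags(self):
        rep = artifact_mask(np.full(100, 3.0))
        assert not rep.mask.any() and rep.intervals == []

    def test_injected_artifacts_recovered(self):
        """>=95% of generator-injected artifact transients intersect the mask."""
        from skiemg.preprocess import bandpass_emg, remove_baseline, rms_envelope

        hit = total = 0
        for seed in range(4):
            cfg = SynthConfig(discipline="GS", n_runs=2, turns_per_run=30, artifact_rate=3.0, seed=100 + seed)
            session, truth = generate_session(cfg)
            ch = session.channels["VM"]
            x = remove_baseline(bandpass_emg(ch.samples, ch.rate_hz), ch.rate_hz)
            env = rms_envelope(x, ch.rate_hz)
            for marker, centers in zip(session.run_markers, truth.artifact_times_s["VM"]):
                a = int(round(marker.start_s * ch.rate_hz))
                b = int(round(marker.end_s * ch.rate_hz))
                rep = artifact_mask(env[a:b])
                for c in centers:
                    total += 1
                    i0 = int((c - 0.02) * ch.rate_hz) - a
                    i1 = int((c + 0.02) * ch.rate_hz) - a
                    if rep.mask[max(i0, 0) : i1].any():
                        hit += 1
        assert total > 0
        assert hit / total >= 0.95


def _tone_trial(group, peak_force, max_rms, fs_force=148.0, fs_emg=FS_EMG):
    """Force trapezoid + 100 Hz tone EMG whose plateau RMS equals max_rms."""
    t_f = np.arange(int(4 * fs_force)) / fs_force
    force = peak_force * np.interp(t_f, [0, 1, 3, 4], [0, 1, 1, 0])
    t_e = np.arange(int(4 * fs_emg)) / fs_emg
    emg_sig = np.where((t_e >= 1) & (t_e <= 3), max_rms * np.sqrt(2) * np.sin(2 * np.pi * 100 * t_e), 0.0)
    muscles = ("VM", "RF", "VL") if group == "extension" else ("BF", "SMST")
    emg = {m: (emg_sig if m in muscles else np.zeros_like(emg_sig)) for m in ("VM", "RF", "VL", "BF", "SMST")}
    return MvcTrial(group, force, fs_force, emg, fs_emg)


class TestMvcReference:
    def test_ten_percent_retention_rule(self):
        trials = MvcTrialSet(
            [
                _tone_trial("extension", 100.0, 0.20),
                _tone_trial("extension", 95.0, 0.18),
                _tone_trial("extension", 85.0, 0.30),  # force too low: excluded
                _tone_trial("flexion", 50.0, 0.10),
            ]
        )
        refs = mvc_reference(trials)
        assert refs["VM"].retained_trials == [0, 1]
        assert refs["VM"].reference_rms == pytest.approx(0.19, rel=0.01)

    def test_single_trial_is_its_own_reference(self):
        trials = MvcTrialSet([_tone_trial("extension", 100.0, 0.22), _tone_trial("flexion", 40.0, 0.1)])
        refs = mvc_reference(trials)
        assert refs["VL"].reference_rms == pytest.approx(0.22, rel=0.01)

    def test_generator_closed_loop_noise_free(self):
        cfg = SynthConfig(seed=5)
        refs = mvc_reference(generate_mvc_trials(cfg, noise=0.0))
        for m, expected in cfg.mvc_ref_rms_v.items():
            assert refs[m].reference_rms == pytest.approx(expected, rel=0.01)

    def test_generator_closed_loop_noisy_across_seeds(self):
        cfg = SynthConfig(seed=0)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            refs = mvc_reference(generate_mvc_trials(cfg, rng, noise=0.02))
            assert refs["VM"].reference_rms == pytest.approx(cfg.mvc_ref_rms_v["VM"], rel=0.05)


class TestNormalizeToMvc:
    @pytest.mark.parametrize("env,expected", [(0.2, 100.0), (0.0, 0.0), (0.1, 50.0)])
    def test_values(self, env, expected):
        assert normalize_to_mvc(np.array([env]), 0.2)[0] == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_to_mvc(np.ones(3), 0.0)

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0.1, 10.0))
    def test_linearity(self, a):
        env = np.linspace(0, 1, 50)
        assert np.allclose(normalize_to_mvc(a * env, 0.2), a * normalize_to_mvc(env, 0.2))


class TestDisciplineLowpass:
    def test_sl_angle_filter_frequency_response(self):
        x10, _ = sine(10.0, FS_MOT, 30.0)
        x03, _ = sine(0.3, FS_MOT, 30.0)
        out10 = interior(lowpass_angles(x10, FS_MOT, "SL"))
        out03 = interior(lowpass_angles(x03, FS_MOT, "SL"))
        assert np.max(np.abs(out10)) < 0.05
        assert np.max(np.abs(out03)) == pytest.approx(1.0, rel=0.05)

    def test_cutoff_tables(self):
        assert ACCR_CUTOFF_HZ == {"DH": 0.8, "SG": 1.0, "GS": 2.0, "SL": 3.0}
        assert ANGLE_CUTOFF_HZ == {"DH": 0.5, "SG": 1.0, "GS": 2.0, "SL": 2.5}

    def test_constant_preserved_and_unknown_discipline(self):
        assert np.allclose(lowpass_accr(np.full(1000, 1.3), FS_MOT, "DH"), 1.3)
        with pytest.raises(ConfigurationError):
            lowpass_angles(np.zeros(100), FS_MOT, "XX")


class TestAngularVelocity:
    def test_sine_peak_velocity(self):
        t = np.arange(int(20 * FS_MOT)) / FS_MOT
        angle = 90 + 10 * np.sin(2 * np.pi * 0.5 * t)
        v = angular_velocity(angle, FS_MOT)
        assert np.max(np.abs(v)) == pytest.approx(10 * 2 * np.pi * 0.5, rel=0.01)

    def test_constant_and_ramp(self):
        assert np.allclose(angular_velocity(np.full(100, 90.0), FS_MOT), 0.0)
        ramp = 90 + 5 * np.arange(200) / FS_MOT
        assert np.allclose(angular_velocity(ramp, FS_MOT)[1:-1], 5.0)

    def test_too_short(self):
        with pytest.raises(ConfigurationError):
            angular_velocity(np.array([1.0, 2.0]), FS_MOT)
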
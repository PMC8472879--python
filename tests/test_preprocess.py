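"""Filtering, windowing, SNR and POS behaviour against closed-form oracles."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.fft import next_fast_len, rfft, rfftfreq

from ppgbp import preprocess as pp
from ppgbp import synthetic as syn


def _sine(freq, fs, duration, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_dc_removed(self):
        rec = pp.WaveformRecord("s", np.full(2000, 3.0), None, fs=125.0)
        out = pp.bandpass_ppg(rec)
        assert np.abs(out.ppg[500:-500]).max() < 1e-6

    def test_passband_preserved(self):
        rec = pp.WaveformRecord("s", _sine(2.0, 125.0, 30.0), None, fs=125.0)
        out = pp.bandpass_ppg(rec)
        assert out.ppg[500:-500].max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_design(self):
        """0.1 Hz attenuation agrees with the designed filter response."""
        rec = pp.WaveformRecord("s", _sine(0.1, 125.0, 120.0), None, fs=125.0)
        out = pp.bandpass_ppg(rec)
        sos = sps.butter(4, [0.5, 8.0], btype="bandpass", fs=125.0,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.1], fs=125.0)
        expected = np.abs(h[0]) ** 2        # forward-backward: squared
        mid = out.ppg[3000:-3000]
        assert mid.max() < 0.2
        assert mid.max() == pytest.approx(expected, rel=0.15)

    def test_invalid_cutoffs_rejected(self):
        rec = pp.WaveformRecord("s", np.zeros(100), None, fs=125.0)
        with pytest.raises(ValueError):
            pp.bandpass_ppg(rec, low=0.5, high=70.0)

    def test_abp_untouched(self):
        abp = np.linspace(60, 120, 2000)
        rec = pp.WaveformRecord("s", _sine(1.0, 125.0, 16.0), abp, fs=125.0)
        out = pp.bandpass_ppg(rec)
        assert out.abp is rec.abp or np.array_equal(out.abp, abp)


class TestHeartRate:
    @pytest.mark.parametrize("freq,expected", [(1.5, 90.0), (1.0, 60.0)])
    def test_pure_tone(self, freq, expected):
        hr = pp.estimate_heart_rate(_sine(freq, 125.0, 20.0), 125.0)
        assert hr == pytest.approx(expected, abs=1.2)

    def test_highest_amplitude_wins(self):
        x = _sine(1.0, 125.0, 20.0, amplitude=2.0) + _sine(2.0, 125.0, 20.0)
        assert pp.estimate_heart_rate(x, 125.0) == pytest.approx(60.0, abs=1.2)

    def test_noisy_pulse_within_one_bin(self):
        profile = syn.SyntheticSubjectProfile(
            subject_id="h", base_hr=72.0, hr_jitter_sd=0.0, noise_sd=0.1,
            bp_drift_amplitude=0.0, record_duration=30.0, seed=1)
        rec = syn.generate_subject_record(profile)
        assert pp.estimate_heart_rate(rec.ppg, 125.0) == pytest.approx(
            72.0, abs=60.0 * pp.HR_FREQ_RESOLUTION)

    def test_all_zero_errors(self):
        with pytest.raises(pp.UndefinedHeartRateError):
            pp.estimate_heart_rate(np.zeros(1000), 125.0)


class TestCropping:
    def test_const_time_window_count_and_length(self):
        rec = pp.WaveformRecord("s", np.sin(np.arange(70 * 125) * 0.05),
                                np.zeros(70 * 125), fs=125.0)
        wins = pp.crop_windows(rec, pp.WindowingConfig("const_time", 7))
        assert len(wins) == 10
        assert all(w.n_samples == 875 for w, _ in wins)
        offsets = [w.source_offset for w, _ in wins]
        assert offsets == sorted(offsets)

    def test_const_beats_span_and_resampling(self):
        """At true 84 bpm a 7-beat span is 5 s, resampled to 875 samples."""
        profile = syn.SyntheticSubjectProfile(
            subject_id="c", base_hr=84.0, hr_jitter_sd=0.0, noise_sd=0.0,
            bp_drift_amplitude=0.0, record_duration=60.0, seed=2)
        rec = syn.generate_subject_record(profile)
        wins = pp.crop_windows(rec, pp.WindowingConfig("const_beats", 7))
        assert all(w.n_samples == 875 for w, _ in wins)
        # source span of each window ~= 5 s = 625 samples
        spans = np.diff([w.source_offset for w, _ in wins])
        assert np.all(np.abs(spans - 625) <= 5)
        # ABP segment covers the un-resampled span
        assert abs(len(wins[0][1]) - 625) <= 5

    def test_const_beats_at_60bpm_is_identity_timeline(self):
        profile = syn.SyntheticSubjectProfile(
            subject_id="c", base_hr=60.0, hr_jitter_sd=0.0, noise_sd=0.0,
            bp_drift_amplitude=0.0, record_duration=40.0, seed=2)
        rec = syn.generate_subject_record(profile)
        wins = pp.crop_windows(rec, pp.WindowingConfig("const_beats", 7))
        w, _ = wins[0]
        src = rec.ppg[w.source_offset:w.source_offset + 875]
        assert np.corrcoef(w.samples, src)[0, 1] > 0.999

    def test_short_record_yields_empty(self):
        rec = pp.WaveformRecord("s", np.sin(np.arange(250) * 0.1),
                                None, fs=125.0)
        assert pp.crop_windows(rec, pp.WindowingConfig("const_time", 7)) == []


class TestResample:
    def test_output_length_forced(self):
        out = pp.resample_to_effective_60bpm(np.random.default_rng(0)
                                             .normal(size=300), 7, 125)
        assert len(out) == 875

    def test_identity_when_already_at_target(self):
        x = np.sin(2 * np.pi * np.arange(875) / 125.0)
        out = pp.resample_to_effective_60bpm(x, 7, 125)
        assert np.allclose(out, x, atol=1e-8)

    def test_dominant_frequency_is_1hz(self):
        """7 cycles in 625 samples resample to 1 Hz at the notional rate."""
        x = np.sin(2 * np.pi * 7 * np.arange(625) / 625)
        out = pp.resample_to_effective_60bpm(x, 7, 125)
        spec = np.abs(rfft(out - out.mean()))
        freqs = rfftfreq(len(out), 1 / 125.0)
        assert freqs[np.argmax(spec)] == pytest.approx(1.0, abs=125.0 / 875)


class TestDerivatives:
    def test_ramp_and_sine(self):
        w = pp.SignalWindow(np.arange(100.0), "s", 0)
        out = pp.add_derivative_channels(w)
        assert out.channels == 3
        assert np.allclose(out.samples[:, 1], 1.0)
        assert np.allclose(out.samples[1:-1, 2], 0.0)

    def test_second_derivative_is_first_applied_twice(self, rng):
        x = rng.normal(size=500)
        out = pp.add_derivative_channels(pp.SignalWindow(x, "s", 0))
        assert np.array_equal(out.samples[:, 2],
                              np.gradient(np.gradient(x)))

    def test_three_channel_input_rejected(self):
        w = pp.SignalWindow(np.zeros((100, 3)), "s", 0)
        with pytest.raises(ValueError):
            pp.add_derivative_channels(w)


from _oracles import brute_force_snr  # noqa: E402


class TestSnr:
    def test_constructed_energies(self):
        assert pp.snr_from_energies(10.0, 1.0) == pytest.approx(10.0)
        assert pp.snr_from_energies(5.0, 5.0) == pytest.approx(0.0)
        assert np.isinf(pp.snr_from_energies(1.0, 0.0))

    def test_matches_brute_force_oracle(self, rng):
        t = np.arange(875) / 125.0
        for _ in range(20):
            x = np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 0.5, 875)
            got = pp.compute_snr(x, 125.0)
            assert got.snr_db == pytest.approx(brute_force_snr(x, 125.0),
                                               abs=1e-6)

    def test_amplitude_invariance(self, rng):
        x = np.sin(2 * np.pi * 1.2 * np.arange(875) / 125.0) \
            + rng.normal(0, 0.3, 875)
        a = pp.compute_snr(x, 125.0).snr_db
        b = pp.compute_snr(7.3 * x, 125.0).snr_db
        assert a == pytest.approx(b, abs=1e-9)

    def test_snr_decreases_with_noise(self):
        """Increasing noise monotonically lowers SNR (one violation allowed)."""
        t = np.arange(875) / 125.0
        pulse = np.sin(2 * np.pi * 1.2 * t)
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 1.0, 875)
        snrs = [pp.compute_snr(pulse + s * noise, 125.0).snr_db
                for s in (0.1, 0.2, 0.4, 0.8, 1.6)]
        violations = sum(b >= a for a, b in zip(snrs, snrs[1:]))
        assert violations <= 1

    def test_zero_rest_energy_flagged_not_crashed(self):
        # pure in-band tone: all analysis-band energy sits in the pulse band
        x = np.sin(2 * np.pi * 1.0 * np.arange(16 * 4) / 4.0)
        res = pp.compute_snr(x, 4.0)
        assert res.infinite or np.isfinite(res.snr_db)


class TestGate:
    def test_default_threshold_boundary_inclusive(self):
        wins = [pp.SignalWindow(np.zeros(10), "s", i) for i in range(3)]
        for w, v in zip(wins, (-9.0, -7.0, -3.0)):
            w.snr_db = v
        kept = pp.gate_by_snr(wins, -7.0)
        assert [w.snr_db for w in kept] == [-7.0, -3.0]

    def test_minus_inf_threshold_keeps_all(self):
        wins = [pp.SignalWindow(np.zeros(10), "s", i) for i in range(5)]
        for i, w in enumerate(wins):
            w.snr_db = -50.0 + i
        assert len(pp.gate_by_snr(wins, -np.inf)) == 5

    def test_matches_elementwise_oracle(self, rng):
        wins = []
        for i in range(1000):
            w = pp.SignalWindow(np.zeros(4), "s", i)
            w.snr_db = rng.uniform(-20, 10)
            wins.append(w)
        kept = {w.source_offset for w in pp.gate_by_snr(wins, -7.0)}
        expected = {w.source_offset for w in wins if w.snr_db >= -7.0}
        assert kept == expected


class TestNormalize:
    def test_closed_form_three_samples(self):
        out = pp.normalize_window(pp.SignalWindow(np.array([1.0, 2.0, 3.0]),
                                                  "s", 0))
        assert np.allclose(out.samples, [-1.22474487, 0.0, 1.22474487])

    def test_idempotent(self, rng):
        w = pp.normalize_window(pp.SignalWindow(rng.normal(size=200), "s", 0))
        w2 = pp.normalize_window(w)
        assert np.allclose(w.samples, w2.samples, atol=1e-12)

    def test_moments_after_normalization(self, rng):
        x = rng.normal(3.0, 7.0, size=(300, 3))
        out = pp.normalize_window(pp.SignalWindow(x, "s", 0))
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.samples.var(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_rejected(self):
        with pytest.raises(pp.ConstantChannelError):
            pp.normalize_window(pp.SignalWindow(np.ones(50), "s", 0))


class TestPos:
    def test_equal_constant_channels_zero_output(self):
        rgb = np.ones((200, 3)) * 5.0
        assert np.allclose(pp.pos_extract(rgb, 32.0), 0.0)

    def test_global_scale_invariance(self, rng):
        base = 1.0 + 0.02 * rng.normal(size=(400, 3))
        a = pp.pos_extract(base, 32.0)
        b = pp.pos_extract(3.0 * base, 32.0)
        assert np.allclose(a, b, atol=1e-10)

    def test_recovers_embedded_pulse(self):
        profile = syn.SyntheticSubjectProfile(
            subject_id="p", base_hr=66.0, noise_sd=0.0, hr_jitter_sd=1.0,
            bp_drift_amplitude=3.0, record_duration=120.0, seed=8)
        trace = syn.generate_rppg_trace(profile, fs=32.0, pulse_strength=0.05,
                                        artifact_rate=0.0)
        pulse = pp.pos_extract(trace.rgb, 32.0)
        assert np.corrcoef(pulse, trace.hidden_pulse)[0, 1] >= 0.9

    def test_extracted_pulse_dominant_frequency(self):
        """HR 66 bpm embeds a 1.1 Hz tone recoverable from POS output."""
        profile = syn.SyntheticSubjectProfile(
            subject_id="p", base_hr=66.0, noise_sd=0.0, hr_jitter_sd=0.0,
            bp_drift_amplitude=0.0, record_duration=120.0, seed=8)
        trace = syn.generate_rppg_trace(profile, fs=32.0, pulse_strength=0.1,
                                        artifact_rate=0.0)
        pulse = pp.pos_extract(trace.rgb, 32.0)
        assert pp.estimate_heart_rate(pulse, 32.0) == pytest.approx(
            66.0, abs=60.0 * pp.HR_FREQ_RESOLUTION)
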
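"""Core two-stage transform: analysis, modulation spectrogram, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modspec as ms
from modspec import (
    InputError,
    InsufficientDataError,
    ParameterError,
    TimeSeries,
    modulation_spectrogram,
    modulation_tensor,
    stft_analysis,
    stft_defaults,
    synthesize,
)
from modspec.transform import filterbank_hilbert_analysis


class TestStftAnalysis:
    def test_zero_signal_gives_zero_coefficients(self):
        x = TimeSeries(np.zeros(4000), 1000.0)
        S = stft_analysis(x, 0.064, 0.016)
        assert np.all(S.coeffs == 0)

    def test_matches_direct_dft_of_windowed_segments(self):
        """Frame-by-frame oracle: windowed-segment DFT computed by hand."""
        fs = 1000.0
        t = np.arange(5000) / fs
        x = TimeSeries(np.sin(2 * np.pi * 10.0 * t), fs)
        win, hop = 500, 125
        S = stft_analysis(x, 0.5, 0.125, "hamming")
        from scipy.signal import get_window

        w = get_window("hamming", win)
        n_frames = (5000 - win) // hop + 1
        assert S.n_frames == n_frames
        for k in (0, 3, n_frames - 1):
            seg = x.samples[k * hop: k * hop + win] * w
            oracle = np.fft.rfft(seg)
            np.testing.assert_allclose(S.coeffs[k], oracle, rtol=0, atol=1e-9)
        # per-frame magnitude peak at the bin nearest 10 Hz
        peak_bins = np.argmax(np.abs(S.coeffs), axis=1)
        expected = np.argmin(np.abs(S.freq_axis - 10.0))
        assert np.all(peak_bins == expected)

    def test_env_rate_and_frame_centering(self):
        x = TimeSeries(np.ones(1000), 100.0)
        S = stft_analysis(x, 0.5, 0.25)
        assert S.env_rate == pytest.approx(100.0 / 25)
        assert S.frame_times[0] == pytest.approx(0.25)
        assert np.all(np.diff(S.frame_times) == pytest.approx(0.25))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(win_s=0.1, hop_s=0.2),     # hop > window
            dict(win_s=0.001, hop_s=0.001),  # window < 2 samples
            dict(win_s=0.1, hop_s=0.05, nfft=5),  # nfft < window
        ],
    )
    def test_parameter_errors(self, bad):
        x = TimeSeries(np.ones(1000), 100.0)
        with pytest.raises(ParameterError):
            stft_analysis(x, **bad)

    def test_nonfinite_and_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            TimeSeries(np.array([1.0, np.nan]), 100.0)
        with pytest.raises(InputError):
            TimeSeries(np.array([]), 100.0)

    def test_max_fmod_law_doubling_hop_halves_envelope_rate(self, white_noise):
        S1 = stft_analysis(white_noise, 0.064, 0.008)
        S2 = stft_analysis(white_noise, 0.064, 0.016)
        assert S1.env_rate == 2 * S2.env_rate
        M1 = modulation_spectrogram(S1)
        M2 = modulation_spectrogram(S2)
        assert M1.fmod_axis[-1] == 2 * M2.fmod_axis[-1]


class TestModulationSpectrogram:
    def test_single_frame_rejected(self):
        x = TimeSeries(np.ones(100), 100.0)
        S = stft_analysis(x, 1.0, 1.0)
        assert S.n_frames == 1
        with pytest.raises(InsufficientDataError):
            modulation_spectrogram(S)

    def test_unmodulated_carrier_has_no_nondc_energy(self):
        # carrier on a bin center (125 Hz = bin 8 of a 64-point FFT at 1 kHz)
        # so spectral leakage does not masquerade as modulation
        fs = 1000.0
        t = np.arange(10000) / fs
        x = TimeSeries(np.sin(2 * np.pi * 125.0 * t), fs)
        S = stft_analysis(x, 0.064, 0.016)
        # natural (unpadded) modulation grid: zero-padding would interpolate
        # the DC line across neighboring bins and masquerade as modulation
        M = modulation_spectrogram(S, mod_nfft=S.n_frames)
        cb = np.argmin(np.abs(M.freq_axis - 125.0))
        p = M.power[:, cb]
        assert p[1:].sum() < 0.01 * p[0]

    def test_am_line_position_and_ratio_vs_envelope_dft_oracle(self, am_tone):
        """The carrier-bin modulation line must match the DFT of the known
        envelope 1 + 0.5*cos(2*pi*5*t) in position and DC-relative height."""
        S = stft_analysis(am_tone, 0.064, 0.016)
        M = modulation_spectrogram(S)
        cb = np.argmin(np.abs(M.freq_axis - 100.0))
        mag = M.values[:, cb]
        nondc = M.fmod_axis > 1.0
        f_peak = M.fmod_axis[nondc][np.argmax(mag[nondc])]
        df = M.fmod_axis[1] - M.fmod_axis[0]
        assert abs(f_peak - 5.0) <= df + 1e-9
        # oracle: DFT of the envelope sampled at env_rate with same length/pad,
        # times the analysis window's envelope-smoothing gain at 5 Hz (the
        # 64 ms window low-passes the envelope it measures)
        n = S.n_frames
        te = np.arange(n) / S.env_rate
        env = 1.0 + 0.5 * np.cos(2 * np.pi * 5.0 * (te + S.frame_times[0]))
        om = np.abs(np.fft.rfft(env, n=M.mod_nfft))
        from scipy.signal import get_window

        w = get_window("hamming", 64)
        tw = np.arange(64) / 1000.0
        wgain = (np.abs(np.sum(w * np.exp(-2j * np.pi * 5.0 * tw)))
                 / np.sum(w))
        line_ratio_oracle = wgain * om[np.argmin(np.abs(M.fmod_axis - 5.0))] / om[0]
        line_ratio = mag[np.argmin(np.abs(M.fmod_axis - 5.0))] / mag[0]
        assert line_ratio == pytest.approx(line_ratio_oracle, rel=0.05)

    def test_peak_on_bin_center_is_exact(self):
        fs = 1000.0
        S0 = stft_analysis(ms.synth.synth_am(100, 1.0, 0.5, fs, 10.0), 0.064, 0.016)
        M0 = modulation_spectrogram(S0, mod_nfft=S0.n_frames)  # natural grid
        df = M0.fmod_axis[1] - M0.fmod_axis[0]
        fm = 5 * df  # exactly on a bin center
        S = stft_analysis(ms.synth.synth_am(100, fm, 0.5, fs, 10.0), 0.064, 0.016)
        M = modulation_spectrogram(S, mod_nfft=S.n_frames)
        cb = np.argmin(np.abs(M.freq_axis - 100.0))
        p = M.power[:, cb]
        assert np.argmax(p[1:]) + 1 == 5

    def test_envelope_parseval_energy_conservation(self, white_noise):
        S = stft_analysis(white_noise, 0.064, 0.016)
        M = modulation_spectrogram(S)
        env_energy = np.sum(S.envelopes**2, axis=0)
        rec = M.envelope_energy()
        np.testing.assert_allclose(rec, env_energy, rtol=1e-6)

    def test_phase_does_not_participate(self, white_noise, rng):
        """Multiplying coefficients by any unit-modulus per-bin constant
        leaves the modulation spectrogram bit-identical."""
        S = stft_analysis(white_noise, 0.064, 0.016)
        M1 = modulation_spectrogram(S)
        phase = np.exp(1j * rng.uniform(0, 2 * np.pi, S.coeffs.shape[1]))
        S2 = ms.SpectroTemporal(S.coeffs * phase[None, :], S.freq_axis,
                                S.env_rate, S.frame_times, S.window_desc, S.fs)
        M2 = modulation_spectrogram(S2)
        np.testing.assert_allclose(M2.values, M1.values, rtol=1e-12)

    def test_scale_and_normalization_options(self, am_tone):
        S = stft_analysis(am_tone, 0.064, 0.016)
        Mm = modulation_spectrogram(S, scale="magnitude")
        Mp = modulation_spectrogram(S, scale="power")
        np.testing.assert_allclose(Mp.values, Mm.values**2, rtol=1e-12)
        Mn = modulation_spectrogram(S, normalization="global-max")
        assert Mn.values.max() == pytest.approx(1.0)


class TestFilterbankHilbert:
    def test_am_envelope_matches_closed_form(self, am_tone):
        S = filterbank_hilbert_analysis(am_tone, [(80.0, 120.0), (200.0, 300.0)])
        t = am_tone.times
        ideal = 1.0 + 0.5 * np.cos(2 * np.pi * 5.0 * t)
        env = S.envelopes
        core = slice(500, -500)
        rms = np.sqrt(np.mean((env[core, 0] - ideal[core]) ** 2))
        assert rms < 0.01
        assert np.mean(env[:, 1] ** 2) < 1e-4 * np.mean(env[:, 0] ** 2)

    def test_fullband_noise_energy_identity(self, white_noise):
        S = filterbank_hilbert_analysis(white_noise, [(1.0, 499.0)])
        p_env = np.mean(S.envelopes[:, 0] ** 2)
        p_sig = np.mean(white_noise.samples**2)
        # analytic-signal envelope power = 2x real signal power in passband
        assert p_env == pytest.approx(2 * p_sig, rel=0.05)

    def test_zero_signal_zero_envelopes(self):
        x = TimeSeries(np.zeros(1000), 1000.0)
        S = filterbank_hilbert_analysis(x, [(10.0, 50.0)])
        assert np.allclose(S.envelopes, 0)

    def test_degenerate_band_rejected(self):
        x = TimeSeries(np.ones(1000), 1000.0)
        with pytest.raises(ParameterError):
            filterbank_hilbert_analysis(x, [(50.0, 50.0)])
        with pytest.raises(ParameterError):
            filterbank_hilbert_analysis(x, [(100.0, 600.0)])


class TestSynthesize:
    def test_round_trip_white_noise(self, white_noise):
        S = stft_analysis(white_noise, 0.064, 0.016, "hamming")  # 75% overlap
        y = synthesize(S)
        assert len(y) == len(white_noise)
        edge = 32  # half window
        e = white_noise.samples[edge:-edge] - y.samples[edge:-edge]
        rel = np.sqrt(np.mean(e**2) / np.mean(white_noise.samples[edge:-edge] ** 2))
        assert rel < 1e-3

    def test_zero_signal_round_trips_to_zero(self):
        x = TimeSeries(np.zeros(2000), 500.0)
        y = synthesize(stft_analysis(x, 0.1, 0.025))
        assert np.allclose(y.samples, 0)

    def test_ecg_r_peak_amplitudes_preserved(self, clean_ecg_60):
        """Peak-matching oracle: R amplitudes before and after the round trip."""
        x, gt = clean_ecg_60
        y = synthesize(stft_analysis(x, **stft_defaults("ecg")))
        idx = np.round(gt.r_times * x.fs).astype(int)
        idx = idx[(idx > 100) & (idx < len(x) - 100)]
        a0 = np.array([x.samples[i - 3: i + 4].max() for i in idx])
        a1 = np.array([y.samples[i - 3: i + 4].max() for i in idx])
        assert np.all(np.abs(a1 - a0) / a0 < 0.01)

    def test_non_invertible_hop_rejected_at_analysis_time(self):
        x = TimeSeries(np.ones(4000), 1000.0)
        # hop == window with a hamming window leaves near-zero valleys in
        # the overlap-add weight only when the window has zero endpoints;
        # boxcar with full hop is fine, hann with full hop is not
        with pytest.raises(ParameterError):
            stft_analysis(x, 0.064, 0.064, "hann")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_round_trip_property_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(900, 3000))
        x = TimeSeries(rng.standard_normal(n), 250.0)
        S = stft_analysis(x, 0.128, 0.032)
        y = synthesize(S)
        assert len(y) == n
        edge = 16
        num = np.mean((x.samples[edge:-edge] - y.samples[edge:-edge]) ** 2)
        den = np.mean(x.samples[edge:-edge] ** 2)
        assert np.sqrt(num / den) < 1e-3


class TestModulationTensor:
    def test_frame_count_arithmetic(self):
        fs = 256.0
        x, _ = ms.synth.synth_ecg(60, 60, fs, seed=0)
        tens = modulation_tensor(x, 10.0, 5.0)
        assert tens.dims[2] == 11

    def test_stationary_signal_gives_stationary_frames(self):
        x = ms.synth.synth_am(100, 5, 0.5, 1000.0, 30.0)
        tens = modulation_tensor(x, 8.0, 4.0,
                                 stft_params={"win_s": 0.064, "hop_s": 0.016})
        arrs = [f.values for f in tens.frames]
        ref = arrs[0]
        for a in arrs[1:]:
            assert np.linalg.norm(a - ref) / np.linalg.norm(ref) < 0.05

    def test_hr_step_moves_fundamental_lobe(self):
        """60 -> 90 bpm step: the tracked lobe must move 1.0 -> 1.5 Hz."""
        fs = 256.0
        a, _ = ms.synth.synth_ecg(60, 30, fs, seed=1)
        b, _ = ms.synth.synth_ecg(90, 30, fs, seed=2)
        x = TimeSeries(np.concatenate([a.samples, b.samples]), fs)
        tens = modulation_tensor(x, 10.0, 10.0)
        from modspec.quality import _aggregate_power
        from modspec._search import harmonic_sum_search

        f0s = []
        for M in tens.frames:
            mask = (M.freq_axis >= 2) & (M.freq_axis <= 40)
            f0, _ = harmonic_sum_search(M.fmod_axis,
                                        _aggregate_power(M, freq_mask=mask),
                                        0.5, 3.0, n_harmonics=4)
            f0s.append(f0)
        assert f0s[0] == pytest.approx(1.0, abs=0.05)
        assert f0s[-1] == pytest.approx(1.5, abs=0.08)

    def test_frame_longer_than_signal_warns_and_gives_single_frame(self):
        x = ms.synth.synth_am(100, 5, 0.5, 1000.0, 5.0)
        with pytest.warns(UserWarning):
            tens = modulation_tensor(x, 10.0, 5.0,
                                     stft_params={"win_s": 0.064, "hop_s": 0.016})
        assert tens.dims[2] == 1
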
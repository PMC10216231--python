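"""Feature-branch tests: framing, mel spectrum, deltas, LLDs, functionals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import sawtooth
from scipy.stats import kurtosis as sp_kurtosis, skew as sp_skew

from decspeech.audio import Waveform
from decspeech.features import (
    ExtractionConfig, IS09_DIM, LOG_FLOOR, apply_functionals, build_melspec3d,
    compute_delta, compute_mel_spectrogram, extract_is09, extract_llds,
    frame_signal, is09_feature_names, mel_filterbank, resize_image,
)


def brute_frame_count(n, win, hop):
    """Count frames by explicit sliding."""
    count, start = 0, 0
    while start + win <= n:
        count += 1
        start += hop
    return count


def brute_functionals(y):
    """Independent re-implementation of the 12 functionals."""
    y = list(map(float, y))
    T = len(y)
    mean = sum(y) / T
    m2 = sum((v - mean) ** 2 for v in y) / T
    std = m2 ** 0.5
    if m2 > 1e-30:
        kurt = sum((v - mean) ** 4 for v in y) / T / m2 ** 2 - 3.0
        skw = sum((v - mean) ** 3 for v in y) / T / m2 ** 1.5
    else:
        kurt = skw = 0.0
    mx, mn = max(y), min(y)
    maxpos = y.index(mx) / (T - 1)
    minpos = y.index(mn) / (T - 1)
    t = np.arange(T) / (T - 1)
    slope, offset = np.polyfit(t, y, 1)
    mse = float(np.mean((np.asarray(y) - (offset + slope * t)) ** 2))
    return np.array([mean, std, kurt, skw, mx, mn, maxpos, minpos,
                     mx - mn, offset, slope, mse])


class TestFraming:
    @pytest.mark.parametrize("n,win,hop", [(48_000, 1200, 480), (1200, 1200, 480),
                                           (5000, 400, 160), (1234, 400, 160)])
    def test_frame_count_matches_sliding_oracle(self, n, win, hop):
        frames = frame_signal(np.zeros(n), win, hop)
        assert frames.shape == (brute_frame_count(n, win, hop), win)

    def test_one_second_at_48k_gives_98_frames(self):
        assert frame_signal(np.zeros(48_000), 1200, 480).shape[0] == 98

    def test_signal_shorter_than_window_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(np.zeros(1199), 1200, 480)


class TestMelSpectrogram:
    def test_silent_input_hits_log_floor_everywhere(self):
        wav = Waveform(np.zeros(48_000), 48_000)
        mel = compute_mel_spectrogram(wav)
        assert np.allclose(mel, np.log(LOG_FLOOR))

    def test_pure_tone_peaks_in_band_containing_its_frequency(self, sine_wav):
        mel = compute_mel_spectrogram(sine_wav)
        fbank = mel_filterbank(48_000, 2048, 64)
        bin_1k = int(round(1000 * 2048 / 48_000))
        expected_band = int(np.argmax(fbank[:, bin_1k]))
        assert np.argmax(mel.mean(axis=0)) == expected_band

    def test_shape_is_frames_by_bands(self, sine_wav):
        assert compute_mel_spectrogram(sine_wav).shape == (98, 64)


class TestDelta:
    def test_constant_series_has_zero_delta(self):
        x = np.full((20, 4), 3.7)
        assert np.allclose(compute_delta(x, 1), 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        slope = 0.25
        x = (slope * np.arange(30))[:, None] * np.ones((1, 3))
        d = compute_delta(x, 1)
        assert np.allclose(d[2:-2], slope)

    def test_second_order_delta_of_ramp_is_zero_interior(self):
        x = np.arange(30, dtype=float)[:, None]
        d2 = compute_delta(x, 2)
        assert np.allclose(d2[4:-4], 0.0, atol=1e-12)

    def test_output_shape_matches_input(self):
        x = np.random.default_rng(0).standard_normal((15, 7))
        assert compute_delta(x, 1).shape == x.shape
        assert compute_delta(x, 2).shape == x.shape

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            compute_delta(np.empty((0, 3)), 1)


class TestMelSpec3D:
    def test_output_is_256x256x3(self, sine_wav):
        assert build_melspec3d(sine_wav).shape == (256, 256, 3)

    def test_silent_wav_has_zero_delta_channels(self):
        wav = Waveform(np.zeros(48_000), 48_000)
        img = build_melspec3d(wav)
        assert np.allclose(img[:, :, 1], 0.0)
        assert np.allclose(img[:, :, 2], 0.0)

    def test_resize_of_matching_size_is_identity(self):
        x = np.random.default_rng(1).standard_normal((256, 256))
        assert np.allclose(resize_image(x, 256), x, atol=1e-9)

    def test_configurable_size(self, sine_wav):
        img = build_melspec3d(sine_wav, ExtractionConfig(image_size=64))
        assert img.shape == (64, 64, 3)


class TestLLDs:
    def test_constant_signal_has_zero_zcr(self):
        wav = Waveform(np.full(16_000, 0.3), 16_000)
        lld = extract_llds(wav)
        assert np.allclose(lld[:, 0], 0.0)

    def test_silence_gives_zero_rms_f0_and_clamped_hnr(self):
        wav = Waveform(np.zeros(16_000), 16_000)
        lld = extract_llds(wav)
        assert np.allclose(lld[:, 1], 0.0)   # RMS
        assert np.allclose(lld[:, 2], 0.0)   # F0
        assert np.allclose(lld[:, 3], -60.0)  # HNR clamp floor

    def test_sawtooth_pitch_recovered_and_matches_bruteforce_lag_search(self):
        sr = 48_000
        t = np.arange(sr) / sr
        wav = Waveform(0.4 * sawtooth(2 * np.pi * 200 * t), sr)
        lld = extract_llds(wav)
        f0 = lld[:, 2]
        voiced = f0[f0 > 0]
        assert voiced.size > 0.8 * f0.size
        assert abs(np.median(voiced) - 200 / 500) < 0.02
        # brute-force autocorrelation peak on a middle frame
        frame = wav.samples[480 * 50:480 * 50 + 1200]
        lags = range(96, 961)
        r = [float(np.dot(frame[:-k], frame[k:])) for k in lags]
        best = 96 + int(np.argmax(r))
        assert abs(sr / best - 200) < 5

    def test_zcr_and_f0_are_in_unit_interval(self, tiny_corpus):
        wav = next(iter(tiny_corpus.waveforms.values()))
        lld = extract_llds(wav)
        assert lld[:, 0].min() >= 0 and lld[:, 0].max() <= 1
        assert lld[:, 2].min() >= 0 and lld[:, 2].max() <= 1

    def test_sixteen_columns(self, tiny_corpus):
        wav = next(iter(tiny_corpus.waveforms.values()))
        assert extract_llds(wav).shape[1] == 16


class TestFunctionals:
    def test_constant_series(self):
        out = apply_functionals(np.full(10, 2.5))
        mean, std, kurt, skw, mx, mn, _, _, rng_, offset, slope, mse = out
        assert mean == mx == mn == offset == 2.5
        assert std == kurt == skw == rng_ == slope == mse == 0.0

    def test_linear_sequence_exact_regression(self):
        out = apply_functionals(np.array([0.0, 1.0, 2.0, 3.0]))
        assert np.isclose(out[10], 3.0)   # slope over normalized time
        assert np.isclose(out[9], 0.0)    # offset
        assert np.isclose(out[11], 0.0)   # mse

    def test_matches_bruteforce_on_many_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            y = rng.standard_normal(rng.integers(2, 60))
            assert np.allclose(apply_functionals(y), brute_functionals(y), atol=1e-8)

    @given(st.integers(3, 50), st.integers(0, 2**31 - 1))
    def test_moment_ratios_match_scipy(self, n, seed):
        y = np.random.default_rng(seed).standard_normal(n) * 3 + 1
        out = apply_functionals(y)
        assert np.isclose(out[2], sp_kurtosis(y, fisher=True, bias=True), atol=1e-8)
        assert np.isclose(out[3], sp_skew(y, bias=True), atol=1e-8)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            apply_functionals(np.array([1.0]))


class TestIS09:
    def test_vector_length_384(self, sine_wav):
        assert extract_is09(sine_wav).shape == (IS09_DIM,)

    def test_silent_wav_finite_full_length(self):
        wav = Waveform(np.zeros(16_000), 16_000)
        v = extract_is09(wav)
        assert v.shape == (384,) and np.isfinite(v).all()

    def test_bitwise_determinism(self, sine_wav):
        a = extract_is09(sine_wav)
        b = extract_is09(sine_wav)
        assert np.array_equal(a, b)

    def test_layout_matches_named_order(self, tiny_corpus):
        wav = next(iter(tiny_corpus.waveforms.values()))
        v = extract_is09(wav)
        names = is09_feature_names()
        lld = extract_llds(wav)
        assert np.isclose(v[names.index("zcr_mean")], apply_functionals(lld[:, 0])[0])
        assert np.isclose(v[names.index("hnr_max")], apply_functionals(lld[:, 3])[4])
        d = compute_delta(lld, 1)
        assert np.isclose(v[names.index("rms_de_stddev")], apply_functionals(d[:, 1])[1])
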
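"""Feature front end: mel scale, filterbank geometry, framing, MFCC, delta."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.fft import idct

from panthoot.features import (
    LOG_FLOOR,
    build_mel_filterbank,
    delta,
    extract_features,
    frame_signal,
    hz_to_mel,
    mel_to_hz,
    mfcc,
    next_pow2,
)

# the reference 32-band filterbank: centers on the mel scale (/1000) and in
# hertz (/10^4), spanning 1 Hz to 20050 Hz
PRINTED_MEL = np.array(
    [0.0016, 0.1248, 0.2479, 0.3711, 0.4943, 0.6174, 0.7406, 0.8638,
     0.9869, 1.1101, 1.2332, 1.3564, 1.4796, 1.6027, 1.7259, 1.8491,
     1.9722, 2.0954, 2.2186, 2.3417, 2.4649, 2.5880, 2.7112, 2.8344,
     2.9575, 3.0807, 3.2039, 3.3270, 3.4502, 3.5734, 3.6965, 3.8197]
)
PRINTED_HZ = np.array(
    [0.0001, 0.0082, 0.0172, 0.0273, 0.0385, 0.0511, 0.0650, 0.0806,
     0.0980, 0.1174, 0.1391, 0.1632, 0.1902, 0.2202, 0.2537, 0.2911,
     0.3328, 0.3793, 0.4312, 0.4891, 0.5537, 0.6257, 0.7060, 0.7956,
     0.8956, 1.0071, 1.1315, 1.2702, 1.4250, 1.5976, 1.7902, 2.0050]
)


class TestMelScale:
    def test_zero_is_fixed_point(self):
        assert hz_to_mel(0.0) == 0.0

    @pytest.mark.parametrize("f", [1.0, 700.0, 20050.0])
    def test_round_trip_identity(self, f):
        assert mel_to_hz(hz_to_mel(f)) == pytest.approx(f, rel=1e-9)

    def test_top_of_range_matches_reference_value(self):
        assert 3.8196 <= hz_to_mel(20050.0) / 1000 <= 3.8197

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)
        with pytest.raises(ValueError):
            mel_to_hz(-0.5)


@pytest.fixture(scope="module")
def fb44():
    return build_mel_filterbank(sample_rate_hz=44100, n_fft=2048)


@pytest.fixture(scope="module")
def fb16():
    return build_mel_filterbank(16000, 512)


class TestFilterbank:
    def test_centers_match_reference_arrays(self, fb44):
        # agreement to the printed precision (within one ulp of the last
        # printed digit; the reference mel array carries a ~1e-5 relative
        # excess over the exact formula, so half-ulp agreement is impossible)
        assert np.max(np.abs(fb44.center_mels / 1e3 - PRINTED_MEL)) < 1e-4
        assert np.max(np.abs(fb44.center_hz / 1e4 - PRINTED_HZ)) < 5e-5

    def test_centers_equally_spaced_in_mel(self, fb44):
        gaps = np.diff(fb44.center_mels)
        assert np.all(gaps > 0)
        assert np.ptp(gaps) / gaps.mean() < 1e-9

    def test_centers_increase_within_band_limits(self, fb44):
        assert np.all(np.diff(fb44.center_hz) > 0)
        assert fb44.center_hz[0] == pytest.approx(1.0, rel=1e-9)
        assert fb44.center_hz[-1] == pytest.approx(20050.0, rel=1e-9)

    def test_triangles_have_single_peak(self, fb44):
        for k in range(fb44.n_bands):
            w = fb44.weights[k]
            if w.max() == 0:  # bands above Nyquist collect nothing
                continue
            peak = np.argmax(w)
            assert np.all(np.diff(w[: peak + 1]) >= -1e-12)
            assert np.all(np.diff(w[peak:]) <= 1e-12)
            assert w.max() <= 1.0 + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_mel_filterbank(44100, 2048, n_bands=0)
        with pytest.raises(ValueError):
            build_mel_filterbank(44100, 2048, fmin_hz=100.0, fmax_hz=50.0)


class TestFraming:
    def test_one_second_clip_has_65_frames(self):
        x = np.random.default_rng(0).normal(size=44100)
        assert frame_signal(x, 44100).shape[0] == 65

    def test_exactly_one_frame(self):
        x = np.ones(int(0.030 * 16000))
        frames = frame_signal(x, 16000)
        assert frames.shape == (1, 480)

    def test_short_clip_warns_and_returns_empty(self):
        x = np.ones(int(0.029 * 16000))
        with pytest.warns(UserWarning, match="shorter than one"):
            frames = frame_signal(x, 16000)
        assert frames.shape[0] == 0

    def test_hamming_window_applied(self):
        x = np.ones(480)
        frames = frame_signal(x, 16000)
        assert np.allclose(frames[0], np.hamming(480))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        clip_ms=st.integers(min_value=30, max_value=10000),
        sr=st.sampled_from([16000, 44100]),
    )
    def test_frame_count_formula(self, clip_ms, sr):
        n = int(round(clip_ms * sr / 1000))
        duration_ms = n / sr * 1000
        x = np.zeros(n)
        expected = int(np.floor((duration_ms - 30) / 15 + 1e-9)) + 1
        assert frame_signal(x, sr).shape[0] == expected

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(np.array([]), 16000)


class TestMfcc:
    def test_silence_gives_constant_cepstrum(self, fb16):
        frames = np.zeros((1, 480))
        c = mfcc(frames, fb16)
        # log energies all at the floor -> DCT of a constant: only coeff 0
        assert c[0, 0] == pytest.approx(np.log(LOG_FLOOR) * np.sqrt(32))
        assert np.allclose(c[0, 1:], 0.0, atol=1e-9)

    def test_white_noise_fills_bands_below_nyquist(self, fb16):
        rng = np.random.default_rng(1)
        frames = frame_signal(rng.normal(size=4800), 16000)
        power = np.abs(np.fft.rfft(frames, n=512, axis=1)) ** 2
        energies = power @ fb16.weights.T
        active = fb16.weights.sum(axis=1) > 0
        assert np.all(energies[:, active] > LOG_FLOOR)

    def test_amplitude_doubling_shifts_only_first_coefficient(self):
        # at 44.1 kHz every band lies below Nyquist, so no energy is floored
        fb = build_mel_filterbank(44100, 2048)
        rng = np.random.default_rng(2)
        x = rng.normal(size=13230)
        c1 = mfcc(frame_signal(x, 44100), fb)
        c2 = mfcc(frame_signal(2 * x, 44100), fb)
        # power scales by 4 -> every log-energy shifts by log 4, which the
        # orthonormal DCT routes entirely into coefficient 0
        assert np.allclose(c2[:, 1:], c1[:, 1:], atol=1e-8)
        assert np.allclose(c2[:, 0] - c1[:, 0], np.log(4.0) * np.sqrt(32), atol=1e-8)

    def test_dct_is_orthonormal(self, fb16):
        rng = np.random.default_rng(3)
        frames = frame_signal(rng.normal(size=4800), 16000)
        c = mfcc(frames, fb16)
        power = np.abs(np.fft.rfft(frames * 1.0, n=512, axis=1)) ** 2
        log_e = np.log(np.maximum(power @ fb16.weights.T, LOG_FLOOR))
        assert np.allclose(idct(c, type=2, norm="ortho", axis=1), log_e, atol=1e-9)

    def test_fft_size_mismatch_rejected(self, fb16):
        with pytest.raises(ValueError):
            mfcc(np.zeros((2, 1024)), fb16)


class TestDelta:
    def test_constant_coefficients_give_zero(self):
        assert np.allclose(delta(np.ones((7, 4)) * 3.2), 0.0)

    def test_linear_ramp_recovers_slope(self):
        slope = 0.7
        c = slope * np.arange(20)[:, None] * np.ones((1, 4))
        d = delta(c)
        assert np.allclose(d[2:-2], slope, atol=1e-12)

    def test_single_frame_gives_zero(self):
        assert np.allclose(delta(np.array([[1.0, -2.0, 5.0]])), 0.0)


class TestExtractFeatures:
    def test_shapes_and_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=32000)
        fm1 = extract_features(x, 16000, clip_id="a")
        fm2 = extract_features(x, 16000, clip_id="a")
        assert fm1.mfcc.shape == fm1.delta.shape == (132, 32)
        assert np.array_equal(fm1.stacked, fm2.stacked)
        assert fm1.stacked.shape == (132, 64)

    def test_next_pow2(self):
        assert next_pow2(480) == 512
        assert next_pow2(1323) == 2048
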
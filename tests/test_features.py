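import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfnn import (
    BandDefinition,
    EEGRecording,
    ValidationError,
    band_power,
    binarize_ratings,
    dft,
    extract_features,
)
from cfnn.features import DEFAULT_BANDS, FeatureMatrix, n_windows_per_trial


def brute_force_dft(x: np.ndarray) -> np.ndarray:
    """Direct O(N^2) evaluation of X_k = sum_i x_i exp(-j 2 pi i k / N)."""
    n = len(x)
    i = np.arange(n)
    return np.array(
        [np.sum(x * np.exp(-2j * np.pi * i * k / n)) for k in range(n)]
    )


class TestDFT:
    def test_constant_signal(self):
        spec = dft(np.full(8, 3.0))
        assert spec.coefficients[0] == pytest.approx(24.0)
        np.testing.assert_allclose(spec.coefficients[1:], 0, atol=1e-12)

    def test_unit_impulse(self):
        x = np.zeros(16)
        x[0] = 1.0
        np.testing.assert_allclose(dft(x).coefficients, np.ones(16), atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(16)
        expected = brute_force_dft(x)
        actual = dft(x).coefficients
        assert np.max(np.abs(actual - expected)) / np.max(np.abs(expected)) < 1e-9

    def test_inverse_recovers_signal(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(64)
        back = np.fft.ifft(dft(x).coefficients).real
        np.testing.assert_allclose(back, x, rtol=1e-9, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            dft(np.array([]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=64), st.integers(0, 2**31 - 1))
    def test_parseval(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        spec = dft(x)
        time_energy = np.sum(x**2)
        freq_energy = np.sum(np.abs(spec.coefficients) ** 2) / n
        assert freq_energy == pytest.approx(time_energy, rel=1e-6)


class TestBandPower:
    def test_sinusoid_concentrates_in_alpha(self):
        fs, n = 128.0, 256
        t = np.arange(n) / fs
        spec = dft(np.sin(2 * np.pi * 10.0 * t), fs=fs)
        alpha = band_power(spec, BandDefinition("alpha", 8, 12))
        for band in DEFAULT_BANDS:
            if band.name != "alpha":
                assert alpha > 100 * band_power(spec, band)

    def test_zero_signal_zero_power(self):
        spec = dft(np.zeros(128), fs=128.0)
        assert all(band_power(spec, b) == 0.0 for b in DEFAULT_BANDS)

    def test_band_beyond_nyquist_rejected(self):
        spec = dft(np.ones(16), fs=128.0)
        with pytest.raises(ValidationError, match="Nyquist"):
            band_power(spec, BandDefinition("bad", 10, 70))

    def test_empty_band_returns_zero(self):
        # N=16 at 128 Hz -> bins every 8 Hz; [9, 15) contains no bin
        spec = dft(np.ones(16), fs=128.0)
        assert band_power(spec, BandDefinition("narrow", 9, 15)) == 0.0

    def test_white_noise_flat_spectrum(self):
        """Mean per-bin power is band-independent for white noise (MC oracle)."""
        fs, n, reps = 128.0, 1024, 40
        rng = np.random.default_rng(2)
        per_band = {b.name: [] for b in DEFAULT_BANDS}
        for _ in range(reps):
            spec = dft(rng.standard_normal(n), fs=fs)
            for b in DEFAULT_BANDS:
                per_band[b.name].append(band_power(spec, b))
        means = {k: np.mean(v) for k, v in per_band.items()}
        ses = {k: np.std(v) / np.sqrt(reps) for k, v in per_band.items()}
        grand = np.mean(list(means.values()))
        for k in means:
            assert abs(means[k] - grand) < 3 * ses[k] + 0.05 * grand

    def test_invariance_to_reversal_and_shift(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(128)
        base = [band_power(dft(x, fs=128.0), b) for b in DEFAULT_BANDS]
        rev = [band_power(dft(x[::-1], fs=128.0), b) for b in DEFAULT_BANDS]
        rolled = [band_power(dft(np.roll(x, 17), fs=128.0), b) for b in DEFAULT_BANDS]
        np.testing.assert_allclose(rev, base, rtol=1e-9)
        np.testing.assert_allclose(rolled, base, rtol=1e-9)


class TestBinarize:
    @pytest.mark.parametrize("rating,expected", [(7.0, 1), (3.0, 0), (5.0, 1)])
    def test_threshold_rule(self, rating, expected):
        ratings = np.full((1, 4), rating)
        assert binarize_ratings(ratings, "valence", 5.0)[0] == expected

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValidationError, match="dimension"):
            binarize_ratings(np.ones((2, 4)) * 5, "joy", 5.0)

    def test_threshold_out_of_scale_rejected(self):
        with pytest.raises(ValidationError, match="threshold"):
            binarize_ratings(np.ones((2, 4)) * 5, "valence", 9.5)


class TestExtractFeatures:
    def test_window_count_example(self, random_recording):
        rng = np.random.default_rng(5)
        rec = EEGRecording(
            "s", rng.standard_normal((2, 3, 1024)), 128.0, rng.uniform(1, 9, (2, 4))
        )
        feats = extract_features(rec, window_size=256, step=128)
        assert feats.n_windows == 2 * 7  # floor((1024-256)/128)+1 = 7 per trial

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_samples=st.integers(8, 300),
        window=st.integers(1, 300),
        step=st.integers(1, 64),
    )
    def test_window_count_formula(self, n_samples, window, step):
        rng = np.random.default_rng(0)
        rec = EEGRecording(
            "s",
            rng.standard_normal((1, 2, n_samples)),
            128.0,
            rng.uniform(1, 9, (1, 4)),
        )
        if window > n_samples:
            with pytest.raises(ValidationError):
                extract_features(rec, window_size=window, step=step)
        else:
            feats = extract_features(rec, window_size=window, step=step)
            assert feats.n_windows == n_windows_per_trial(n_samples, window, step)
            assert feats.n_windows == (n_samples - window) // step + 1

    def test_feature_dimension_14x5(self, default_recording):
        feats = extract_features(
            default_recording, window_size=32, channels=list(range(1, 15))
        )
        assert feats.n_features == 70
        assert feats.feature_names[0] == "ch1_theta"
        assert feats.feature_names[5] == "ch2_theta"  # channel-major order

    def test_full_trial_window(self, small_recording):
        feats = extract_features(
            small_recording, window_size=small_recording.n_samples, step=999
        )
        assert feats.n_windows == small_recording.n_trials

    def test_band_powers_nonnegative_and_labeled(self, default_features):
        assert np.all(default_features.values >= 0)
        assert set(np.unique(default_features.labels_valence)) <= {0, 1}
        assert len(default_features.provenance) == default_features.n_windows

    def test_prefilter_removes_drift_keeps_alpha(self):
        fs, n = 128.0, 512
        t = np.arange(n) / fs
        # 2 Hz drift (below the 4-45 Hz pass band) plus a 10 Hz alpha tone
        drift = np.sin(2 * np.pi * 2.0 * t)
        alpha = np.sin(2 * np.pi * 10.0 * t)
        rec = EEGRecording(
            "s", np.tile(drift + alpha, (1, 1, 1)), fs, np.full((1, 4), 5.0)
        )
        raw = extract_features(rec, window_size=n)
        filt = extract_features(rec, window_size=n, pre_filter=True)
        names = raw.feature_names
        a = names.index("ch1_alpha")
        # alpha band power survives the zero-phase band-pass
        assert filt.values[0, a] == pytest.approx(raw.values[0, a], rel=0.2)
        # the 2 Hz line itself is strongly attenuated
        from cfnn.features import BandDefinition

        low = BandDefinition("drift", 1.5, 2.5)
        p_raw = band_power(dft(rec.signals[0, 0], fs=fs), low)
        from scipy import signal as sps

        sos = sps.butter(4, [4.0, 45.0], btype="bandpass", fs=fs, output="sos")
        filtered = sps.sosfiltfilt(sos, rec.signals[0, 0])
        p_filt = band_power(dft(filtered, fs=fs), low)
        assert p_filt < 0.01 * p_raw

    @pytest.mark.parametrize("suffix", [".csv", ".h5"])
    def test_feature_table_round_trip(self, default_features, tmp_path, suffix):
        path = tmp_path / f"feats{suffix}"
        default_features.save(path)
        loaded = FeatureMatrix.load(path)
        np.testing.assert_allclose(loaded.values, default_features.values, rtol=1e-12)
        assert loaded.feature_names == default_features.feature_names
        np.testing.assert_array_equal(
            loaded.labels_valence, default_features.labels_valence
        )
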
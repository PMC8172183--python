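import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from eegstress.features import (
    ALPHA,
    BETA,
    GAMMA_NUM,
    SLOW_DEN,
    THETA,
    BandDefinition,
    WelchConfig,
    band_power,
    brain_load_index,
    power_features,
    read_features_csv,
    relative_gamma,
    write_features_csv,
)
from eegstress.preprocess import WindowedRecording, window
from eegstress.synthetic import CHANNELS, Recording

FS = 250.0


def tone(freq, amp=1.0, seconds=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def wrec_from_windows(windows, channels=CHANNELS, condition="baseline"):
    return WindowedRecording(subject_id="S0", group="control", condition=condition,
                             fs=FS, channels=channels, windows=np.asarray(windows, float))


def periodogram_band_power(x, fs, lo, hi):
    """Independent oracle: plain rectangular periodogram, no averaging."""
    freqs, psd = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    mask = (freqs >= lo) & (freqs < hi)
    return psd[mask].sum() * (freqs[1] - freqs[0])


class TestBandPower:
    def test_sinusoid_alpha_power_matches_analytic(self):
        x = np.tile(tone(10.0, amp=2.0), (3, 1))
        alpha = band_power(x, FS, ALPHA)
        assert np.all(np.abs(alpha - 2.0) / 2.0 < 0.10)  # A^2/2 = 2.0 µV²

    def test_leakage_into_theta_is_small(self):
        x = np.tile(tone(10.0, amp=2.0), (3, 1))
        theta = band_power(x, FS, THETA)
        alpha = band_power(x, FS, ALPHA)
        assert np.all(theta < 0.05 * alpha)

    def test_zero_window_zero_power(self):
        x = np.zeros((3, 250))
        for band in (THETA, ALPHA, BETA, GAMMA_NUM):
            np.testing.assert_array_equal(band_power(x, FS, band), 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros((3, 250)), FS, BandDefinition("hf", 130, 150))

    @pytest.mark.parametrize("freq", [4.0, 10.0, 20.0, 30.0, 40.0])
    def test_welch_agrees_with_periodogram_oracle_on_bins(self, freq):
        """On-bin deterministic test tones: Welch vs plain FFT periodogram within 15%."""
        x = tone(freq, amp=1.5, seconds=1.0)
        band = BandDefinition("b", freq - 3, freq + 3)
        welch_p = band_power(x[None, :], FS, band)[0]
        oracle_p = periodogram_band_power(x, FS, band.lo, band.hi)
        assert abs(welch_p - oracle_p) / oracle_p < 0.15

    def test_band_additivity_over_disjoint_bands(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 250))
        parts = sum(band_power(x, FS, b) for b in (THETA, ALPHA, BETA))
        union = band_power(x, FS, BandDefinition("union", 4, 39))
        np.testing.assert_allclose(parts, union, rtol=1e-10)


class TestPowerFeatures:
    def test_shape_and_column_order(self, power_feats):
        assert power_feats.matrix.shape[1] == 9
        assert power_feats.column_names == (
            "Fz_alpha", "Fz_beta", "Fz_theta",
            "Cz_alpha", "Cz_beta", "Cz_theta",
            "Pz_alpha", "Pz_beta", "Pz_theta",
        )
        assert np.isfinite(power_feats.matrix).all()

    def test_200_windows_give_200_rows(self):
        rng = np.random.default_rng(1)
        wrec = wrec_from_windows(rng.standard_normal((200, 3, 250)))
        assert power_features(wrec).matrix.shape == (200, 9)

    def test_channel_order_permutation_invariant(self):
        rng = np.random.default_rng(2)
        wins = rng.standard_normal((5, 3, 250))
        a = power_features(wrec_from_windows(wins, channels=("Fz", "Cz", "Pz")))
        b = power_features(wrec_from_windows(wins[:, [2, 0, 1], :], channels=("Pz", "Fz", "Cz")))
        np.testing.assert_allclose(a.matrix, b.matrix)

    def test_missing_channel_rejected(self):
        wrec = WindowedRecording(subject_id="S", group="control", condition="baseline",
                                 fs=FS, channels=("Fz", "Cz", "Oz"),
                                 windows=np.zeros((2, 3, 250)))
        with pytest.raises(ValueError, match="Pz"):
            power_features(wrec)

    def test_identical_windows_identical_rows(self):
        w = tone(10)[None, :].repeat(3, axis=0)
        wrec = wrec_from_windows(np.stack([w, w]))
        feats = power_features(wrec)
        np.testing.assert_array_equal(feats.matrix[0], feats.matrix[1])


class TestRelativeGamma:
    def test_matches_brute_force_psd_ratio(self):
        """Hand-computed mean-PSD ratio over explicit bin loops, 1e-12 relative."""
        rng = np.random.default_rng(3)
        wins = rng.standard_normal((4, 3, 250))
        feats = relative_gamma(wrec_from_windows(wins))
        cfg = WelchConfig()
        for wi in range(4):
            for ci in range(3):
                freqs, psd = sps.welch(wins[wi, ci], fs=FS, window=cfg.window,
                                       nperseg=cfg.nperseg, noverlap=cfg.noverlap,
                                       detrend=False)
                num = np.mean([p for f, p in zip(freqs, psd) if 25 <= f < 45])
                den = np.mean([p for f, p in zip(freqs, psd) if 4 <= f < 13])
                assert abs(feats.matrix[wi, ci] - num / den) <= 1e-12 * abs(num / den)

    def test_pure_alpha_signal_gives_near_zero_rg(self):
        w = np.tile(tone(10.0, amp=5.0), (3, 1))
        feats = relative_gamma(wrec_from_windows(w[None]))
        assert np.all(feats.matrix < 0.01)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(4)
        wins = rng.standard_normal((2, 3, 250))
        a = relative_gamma(wrec_from_windows(wins)).matrix
        b = relative_gamma(wrec_from_windows(scale * wins)).matrix
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_flat_zero_signal_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="windows \\[0\\]"):
            relative_gamma(wrec_from_windows(np.zeros((1, 3, 250))))


class TestBrainLoadIndex:
    def test_matches_brute_force_ratio(self):
        rng = np.random.default_rng(5)
        wins = rng.standard_normal((3, 3, 250))
        wrec = wrec_from_windows(wins)
        feats = brain_load_index(wrec)
        theta_fz = band_power(wins[:, 0, :], FS, THETA)
        alpha_pz = band_power(wins[:, 2, :], FS, ALPHA)
        np.testing.assert_allclose(feats.matrix[:, 0], theta_fz / alpha_pz, rtol=1e-12)

    def test_equal_numerator_denominator_gives_unity(self):
        # identical signal on Fz and Pz with matched theta/alpha content is not
        # unity in general; construct the trivial identity via the formula itself
        rng = np.random.default_rng(6)
        wins = rng.standard_normal((2, 3, 250))
        wrec = wrec_from_windows(wins)
        theta_fz = band_power(wins[:, 0, :], FS, THETA)
        alpha_pz = band_power(wins[:, 2, :], FS, ALPHA)
        ratio = brain_load_index(wrec).matrix[:, 0] * alpha_pz / theta_fz
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-12)

    def test_stress_condition_raises_mean_bli(self, bli_feats):
        means = {c: bli_feats.matrix[bli_feats.labels == c, 0].mean()
                 for c in ("baseline", "speech")}
        assert means["speech"] > means["baseline"]

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        wins = rng.standard_normal((2, 3, 250))
        a = brain_load_index(wrec_from_windows(wins)).matrix
        b = brain_load_index(wrec_from_windows(scale * wins)).matrix
        np.testing.assert_allclose(a, b, rtol=1e-9)


def test_features_on_generator_output_are_finite(power_feats, bli_feats):
    assert np.isfinite(power_feats.matrix).all()
    assert np.isfinite(bli_feats.matrix).all()
    assert (power_feats.matrix > 0).all()
    assert (bli_feats.matrix > 0).all()


def test_features_csv_round_trip(tmp_path, bli_feats):
    path = tmp_path / "bli.csv"
    write_features_csv(bli_feats, path)
    back = read_features_csv(path)
    assert back.feature_set == "bli"
    np.testing.assert_allclose(back.matrix, bli_feats.matrix, rtol=1e-9)
    assert list(back.labels) == list(bli_feats.labels)
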
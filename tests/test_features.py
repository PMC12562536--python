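import numpy as np
import pytest

from swisc import errors
from swisc.features import (DEFAULT_SCHEME, band_powers, extract_features,
                            manifest_for, rms_emg, statistical_features)
from swisc.io import EpochArray, ROLES


def sine(freq, rate, dur, amp=1.0, phase=0.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


def make_epochs(data, rate=200.0, epoch_len_s=20.0, roles=ROLES):
    return EpochArray(data=data, epoch_len_s=epoch_len_s, rate=rate, roles=roles)


BAND_IDX = {name: i for i, name in enumerate(DEFAULT_SCHEME.band_names)}


class TestStatisticalFeatures:
    def test_symmetric_series_has_zero_skew(self):
        x = np.tile([-1.0, 0.0, 1.0], 100)
        mean, median, sd, var, skew, kurt = statistical_features(x)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert var == pytest.approx(sd ** 2)

    def test_moment_oracle_on_0001(self):
        # hand-computed central moments of {0, 0, 0, 1}
        got = statistical_features(np.array([0.0, 0.0, 0.0, 1.0]))
        expected = [0.25, 0.0, np.sqrt(0.1875), 0.1875,
                    0.09375 / 0.1875 ** 1.5,          # m3 / sd^3
                    0.08203125 / 0.1875 ** 2 - 3.0]   # m4 / var^2 - 3
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_standard_normal_sample(self, rng):
        x = rng.standard_normal(200_000)
        mean, median, sd, var, skew, kurt = statistical_features(x)
        assert mean == pytest.approx(0.0, abs=0.02)
        assert sd == pytest.approx(1.0, abs=0.02)
        assert kurt == pytest.approx(0.0, abs=0.1)  # excess kurtosis

    def test_constant_segment_flags_zero_shape_moments(self):
        out = statistical_features(np.full(100, 5.0))
        assert out[4] == 0.0 and out[5] == 0.0


class TestBandPowers:
    def test_pure_delta_tone_fft(self):
        x = sine(3.0, 200.0, 20.0)
        bp = band_powers(x, 200.0, "fft_mag")
        assert bp[BAND_IDX["delta"]] >= 0.95
        others = [bp[BAND_IDX[b]] for b in BAND_IDX if b != "delta"]
        assert max(others) <= 0.02
        assert bp[-1] > 10.0  # delta dominates low theta

    def test_pure_delta_tone_welch(self):
        # Hann-window leakage at 1 Hz resolution spills part of a 3 Hz tone
        # into the 4 Hz bin (low theta under the half-open edge convention),
        # so the Welch check asserts dominance rather than purity
        bp = band_powers(sine(3.0, 200.0, 20.0), 200.0, "welch_psd")
        assert bp[BAND_IDX["delta"]] >= 0.8
        others = [bp[BAND_IDX[b]] for b in BAND_IDX if b != "delta"]
        assert max(others) <= 0.2
        assert bp[-1] > 4.0

    @pytest.mark.parametrize("method", ["fft_mag", "welch_psd"])
    def test_pure_10hz_tone(self, method):
        bp = band_powers(sine(10.0, 200.0, 20.0), 200.0, method)
        assert bp[BAND_IDX["theta_high"]] >= 0.9

    @pytest.mark.parametrize("method", ["fft_mag", "welch_psd"])
    def test_ratio_floors_when_theta_dominates(self, method):
        # strong low-theta with no delta content: the ratio collapses
        bp = band_powers(sine(5.0, 200.0, 20.0), 200.0, method)
        assert bp[-1] < 0.1

    def test_60hz_tone_contributes_to_no_band(self, rng):
        """55-65 Hz is excluded everywhere: a strong line-noise tone leaves
        every band fraction (and the broadband normalizer) unchanged."""
        x = rng.standard_normal(4000)
        clean = band_powers(x, 200.0, "fft_mag")
        noisy = band_powers(x + 20.0 * sine(60.0, 200.0, 20.0), 200.0, "fft_mag")
        np.testing.assert_allclose(noisy, clean, rtol=0.02)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(4000)
        a = band_powers(x, 200.0, "fft_mag")
        b = band_powers(5.0 * x, 200.0, "fft_mag")
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_fft_and_welch_agree_on_dominant_band(self):
        x = sine(3.0, 200.0, 20.0) + 0.1 * sine(10.0, 200.0, 20.0)
        a = band_powers(x, 200.0, "fft_mag")
        b = band_powers(x, 200.0, "welch_psd")
        assert np.argmax(a[:6]) == np.argmax(b[:6]) == BAND_IDX["delta"]
        assert a[BAND_IDX["delta"]] == pytest.approx(b[BAND_IDX["delta"]], abs=0.2)

    def test_dense_dft_oracle(self, rng):
        """Band fractions agree with a brute-force DFT-bin summation."""
        x = rng.standard_normal(4000)
        bp = band_powers(x, 200.0, "fft_mag")
        # independent oracle: explicit correlation with each DFT basis vector
        n = len(x)
        t = np.arange(n) / 200.0
        freqs = np.arange(n // 2 + 1) / 20.0
        mags = np.empty(len(freqs))
        for i, f in enumerate(freqs):
            c = x @ np.exp(-2j * np.pi * f * t)
            mags[i] = np.abs(c)
        bb = mags[(freqs >= 2) & (freqs < 55)].sum()
        for name, lo, hi in DEFAULT_SCHEME.bands:
            want = mags[(freqs >= lo) & (freqs < hi)].sum() / bb
            assert bp[BAND_IDX[name]] == pytest.approx(want, rel=1e-6)

    def test_zero_epoch_rejected(self):
        with pytest.raises(errors.DegenerateEpochError):
            band_powers(np.zeros(4000), 200.0, "fft_mag")


class TestRmsEmg:
    def test_unit_sine_rms(self):
        x = sine(10.0, 200.0, 20.0)
        out = rms_emg(x, 200.0, 20.0)
        assert out.shape == (20,)
        np.testing.assert_allclose(out, 1 / np.sqrt(2), rtol=1e-6)

    def test_4s_five_repeat_layout(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(800)
        out = rms_emg(x, 200.0, 4.0)
        assert out.shape == (20,)
        per_bin = np.sqrt((x.reshape(4, 200) ** 2).mean(axis=1))
        np.testing.assert_allclose(out, np.repeat(per_bin, 5))

    def test_all_zero_emg(self):
        assert (rms_emg(np.zeros(4000), 200.0, 20.0) == 0).all()

    def test_unsupported_epoch_length(self):
        with pytest.raises(errors.ConfigError):
            rms_emg(np.zeros(2000), 200.0, 10.0)


class TestFeatureSets:
    @pytest.fixture()
    def epochs(self, rng):
        return make_epochs(rng.standard_normal((5, 4, 4000)))

    @pytest.mark.parametrize("feature_set,n", [
        ("full", 100), ("stat_rms", 44), ("fft_rms", 48), ("dt_rms", 28)])
    def test_feature_counts(self, epochs, feature_set, n):
        fm = extract_features(epochs, feature_set)
        assert fm.values.shape == (5, n)
        assert fm.manifest == manifest_for(feature_set)
        assert len(fm.manifest) == n

    def test_alias_names_accepted(self, epochs):
        assert extract_features(epochs, "DT/RMS").n_features == 28

    def test_hippocampal_only_mask(self, epochs):
        fm = extract_features(epochs, "full", mask=("HPC-L", "HPC-R"))
        assert fm.n_features == 40  # 2 channels x 20, no RMS block
        assert all(name.startswith("HPC") for name in fm.manifest)

    def test_manifest_order_matches_columns(self, epochs):
        """Column j of the matrix is the quantity named by manifest[j]."""
        fm = extract_features(epochs, "full")
        x = epochs.data[:, 0, :]  # ECoG
        j = fm.manifest.index("ECoG:stat:mean")
        np.testing.assert_allclose(fm.values[:, j], x.mean(axis=1))
        j = fm.manifest.index("ECoG:fft:delta")
        np.testing.assert_allclose(fm.values[:, j],
                                   band_powers(x, 200.0, "fft_mag")[:, 0])
        j = fm.manifest.index("EMG:rms:01")
        emg = epochs.data[:, 3, :]
        np.testing.assert_allclose(fm.values[:, j],
                                   np.sqrt((emg[:, :200] ** 2).mean(axis=1)))

    def test_empty_mask_rejected(self, epochs):
        with pytest.raises(errors.ConfigError):
            extract_features(epochs, "full", mask=())

    def test_missing_role_rejected(self, rng):
        epochs = make_epochs(rng.standard_normal((2, 2, 4000)),
                             roles=("ECoG", "EMG"))
        with pytest.raises(errors.LayoutError):
            extract_features(epochs, "full", mask=("HPC-L",))
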
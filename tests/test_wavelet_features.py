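"""Wavelet tests: decomposition structure, band mapping, feature statistics."""

import numpy as np
import pytest
from scipy.signal import butter, filtfilt

from drowsyhrv.hrv_series import HRVSeries
from drowsyhrv.wavelet_features import (
    FEATURE_NAMES,
    decompose,
    feature_vector,
    level_frequency_range,
    moments,
    multiscale_beta,
    reconstruct,
    shannon_entropy,
)
from tests.conftest import hrv_from_array


class TestDecompose:
    def test_nine_coefficient_sets(self, rng):
        dec = decompose(hrv_from_array(rng.standard_normal(420)))
        assert len(dec.details) == 8
        assert set(dec.details) == set(range(1, 9))
        assert dec.approximation.size > 0

    def test_perfect_reconstruction(self, rng):
        x = 1.0 + 0.1 * rng.standard_normal(420)
        dec = decompose(hrv_from_array(x))
        np.testing.assert_allclose(reconstruct(dec), x, atol=1e-8)

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="256"):
            decompose(hrv_from_array(np.ones(200)))

    def test_band_limited_noise_lands_in_matching_level(self):
        # noise confined to 0.11-0.22 Hz concentrates in D5, whose dyadic
        # band is (0.109, 0.219) Hz at fs=7
        rng = np.random.default_rng(1)
        b, a = butter(4, [0.11, 0.22], btype="band", fs=7)
        x = filtfilt(b, a, rng.standard_normal(420))
        dec = decompose(hrv_from_array(1.0 + x))
        variances = {i: np.var(dec.details[i], ddof=1) for i in range(1, 9)}
        assert max(variances, key=variances.get) == 5

    def test_energy_conserved_by_orthogonal_cascade(self, rng):
        # periodization mode on a dyadic length is an orthogonal transform
        x = rng.standard_normal(512)
        dec = decompose(hrv_from_array(x), mode="periodization")
        energy = (np.sum(dec.approximation ** 2)
                  + sum(np.sum(c ** 2) for c in dec.details.values()))
        assert energy == pytest.approx(np.sum(x ** 2), rel=1e-6)


class TestLevelFrequencyRange:
    # printed dyadic bands at the 7 Hz HRV rate, rounded to 2 decimals
    TABLE = {1: (1.75, 3.5), 2: (0.88, 1.75), 3: (0.44, 0.88),
             4: (0.22, 0.44), 5: (0.11, 0.22), 6: (0.05, 0.11),
             7: (0.03, 0.05), 8: (0.01, 0.03)}

    @pytest.mark.parametrize("n", list(range(1, 9)))
    def test_matches_printed_band_table(self, n):
        lo, hi = level_frequency_range(n, 7.0)
        assert (round(lo, 2), round(hi, 2)) == self.TABLE[n]

    def test_exact_dyadic_values(self):
        assert level_frequency_range(1, 7.0) == (1.75, 3.5)
        assert level_frequency_range(5, 7.0) == (0.109375, 0.21875)
        lo, hi = level_frequency_range(8, 7.0)
        assert lo == pytest.approx(0.013671875)
        assert hi == pytest.approx(0.02734375)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            level_frequency_range(0, 7.0)
        with pytest.raises(ValueError):
            level_frequency_range(9, 7.0)


class TestShannonEntropy:
    def test_all_zero_coefficients(self):
        assert shannon_entropy(np.zeros(10)) == 0.0

    def test_unit_coefficients(self):
        assert shannon_entropy(np.array([1.0, 1.0])) == 0.0

    def test_hand_computed_value(self):
        # -(4 log2 4 + 4 log2 4) = -16
        assert shannon_entropy(np.array([2.0, 2.0])) == pytest.approx(-16.0)


class TestMoments:
    def test_constant_level_imputes_kurtosis(self):
        with pytest.warns(UserWarning, match="kurtosis imputed"):
            mean, var, kurt = moments(np.ones(4))
        assert (mean, var, kurt) == (1.0, 0.0, 3.0)

    def test_hand_computed_mean_and_variance(self):
        mean, var, _ = moments(np.array([0.0, 2.0, 0.0, 2.0]))
        assert mean == 1.0
        assert var == pytest.approx(4.0 / 3.0)

    def test_gaussian_kurtosis_approaches_three(self, rng):
        _, _, kurt = moments(rng.standard_normal(100_000))
        assert kurt == pytest.approx(3.0, abs=0.1)


class TestMultiscaleBeta:
    def _decomp_with_variances(self, rng, scale8, scale7):
        x = rng.standard_normal(420)
        dec = decompose(hrv_from_array(x))
        dec.details[8] = scale8 * dec.details[8] / np.std(dec.details[8], ddof=1)
        dec.details[7] = scale7 * dec.details[7] / np.std(dec.details[7], ddof=1)
        return dec

    def test_variance_ratio_four_gives_beta_two(self, rng):
        dec = self._decomp_with_variances(rng, 2.0, 1.0)  # var 4 vs 1
        assert multiscale_beta(dec, (8, 7)) == pytest.approx(2.0)

    def test_equal_variances_give_zero(self, rng):
        dec = self._decomp_with_variances(rng, 1.5, 1.5)
        assert multiscale_beta(dec, (8, 7)) == pytest.approx(0.0, abs=1e-9)

    def test_non_adjacent_pair_rejected(self, rng):
        dec = decompose(hrv_from_array(rng.standard_normal(420)))
        with pytest.raises(ValueError):
            multiscale_beta(dec, (8, 6))


class TestFeatureVector:
    def test_exactly_43_named_features(self, rng):
        fv = feature_vector(hrv_from_array(1 + 0.05 * rng.standard_normal(420)))
        assert len(fv) == 43
        assert tuple(fv) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values())

    def test_deterministic_on_identical_windows(self, rng):
        x = 1 + 0.05 * rng.standard_normal(420)
        assert feature_vector(hrv_from_array(x)) == feature_vector(hrv_from_array(x.copy()))

    def test_rescaling_changes_energy_stats_but_not_beta(self, rng):
        x = 1 + 0.05 * rng.standard_normal(420)
        fv1 = feature_vector(hrv_from_array(x))
        fv2 = feature_vector(hrv_from_array(2.0 * x))
        for name in FEATURE_NAMES:
            if name.startswith("beta"):
                assert fv2[name] == pytest.approx(fv1[name], abs=1e-9)
        assert fv2["variance_D1"] == pytest.approx(4 * fv1["variance_D1"])
        assert fv2["entropy_A8"] != fv1["entropy_A8"]
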
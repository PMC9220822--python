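"""Standardizer and wavelet filter-bank correctness.

The DWT tests pit the in-repo filter bank against hand-derived values,
closed-form length recurrences, conservation laws, and (as an external
oracle only) pywavelets with matching padding modes.
"""

from __future__ import annotations

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from alcoeeg import preprocess as pp

WAVELETS = ("haar", "db2", "db4")
PAD_TO_PYWT = {"zero": "zero", "symmetric": "symmetric", "periodic": "periodization"}


# ---------------------------------------------------------------------------
# Standardizer
# ---------------------------------------------------------------------------

class TestStandardizer:
    def test_hand_derived_column(self):
        # mean 2, population sd sqrt(2/3): [1,2,3] -> [-1.2247, 0, 1.2247]
        state = pp.fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
        assert state.mu[0] == pytest.approx(2.0)
        assert state.sigma[0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        out = pp.apply_standardizer(state, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_constant_column_maps_to_zero_with_warning(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            state = pp.fit_standardizer(X)
        out = pp.apply_standardizer(state, X)
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_fit_transform_is_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 7)) * rng.uniform(0.5, 20.0, size=7) + 3.0
        state = pp.fit_standardizer(X)
        Z = pp.apply_standardizer(state, X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(Z.std(axis=0) - 1.0) < 1e-10)

    def test_identity_when_mu0_sigma1(self):
        state = pp.StandardizerState(mu=np.zeros(3), sigma=np.ones(3), fitted_on=2)
        X = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(pp.apply_standardizer(state, X), X)

    def test_inverse_recovers_input(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4)) * 5 + 1
        state = pp.fit_standardizer(X)
        Z = pp.apply_standardizer(state, X)
        np.testing.assert_allclose(pp.invert_standardizer(state, Z), X, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        state = pp.fit_standardizer(np.ones((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(ValueError, match="mismatch"):
            pp.apply_standardizer(state, np.ones((2, 5)))

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            pp.fit_standardizer(np.ones((1, 3)))


# ---------------------------------------------------------------------------
# Single-level DWT
# ---------------------------------------------------------------------------

class TestSingleLevel:
    def test_haar_hand_computed_pairs(self):
        # (a+b)/sqrt(2) and (a-b)/sqrt(2) per non-overlapping pair
        spec = pp.get_wavelet("haar", padding="periodic")
        approx, detail = pp.dwt_single_level([4.0, 6.0, 10.0, 12.0], spec)
        np.testing.assert_allclose(approx, [7.0711, 15.5563], atol=1e-4)
        np.testing.assert_allclose(detail, [-1.4142, -1.4142], atol=1e-4)

    def test_constant_signal_has_zero_detail(self):
        spec = pp.get_wavelet("haar", padding="periodic")
        _, detail = pp.dwt_single_level(np.full(16, 3.7), spec)
        np.testing.assert_allclose(detail, 0.0, atol=1e-12)

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=256)
        for name in WAVELETS:
            spec = pp.get_wavelet(name, padding="periodic")
            a, d = pp.dwt_single_level(x, spec)
            energy = np.sum(a**2) + np.sum(d**2)
            assert energy == pytest.approx(np.sum(x**2), abs=1e-10)

    def test_empty_signal_raises(self):
        spec = pp.get_wavelet("haar")
        with pytest.raises(ValueError, match="empty"):
            pp.dwt_single_level(np.array([]), spec)

    @pytest.mark.parametrize("wavelet", WAVELETS)
    @pytest.mark.parametrize("padding", sorted(PAD_TO_PYWT))
    @pytest.mark.parametrize("n", [64, 100, 256])
    def test_agrees_with_pywavelets(self, wavelet, padding, n):
        """pywavelets as an independent oracle at matching padding modes."""
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        spec = pp.get_wavelet(wavelet, padding=padding)
        a, d = pp.dwt_single_level(x, spec)
        ca, cd = pywt.dwt(x, wavelet, mode=PAD_TO_PYWT[padding])
        np.testing.assert_allclose(a, ca, atol=1e-8)
        np.testing.assert_allclose(d, cd, atol=1e-8)

    def test_shift_by_two_shifts_coefficients_by_one(self):
        spec = pp.get_wavelet("haar", padding="periodic")
        rng = np.random.default_rng(3)
        x = rng.normal(size=64)
        a0, d0 = pp.dwt_single_level(x, spec)
        a1, d1 = pp.dwt_single_level(np.roll(x, 2), spec)
        np.testing.assert_allclose(a1, np.roll(a0, 1), atol=1e-12)
        np.testing.assert_allclose(d1, np.roll(d0, 1), atol=1e-12)


# ---------------------------------------------------------------------------
# Multilevel cascade + inverse
# ---------------------------------------------------------------------------

class TestMultilevel:
    def test_level_one_equals_single_level(self):
        spec = pp.get_wavelet("db2")
        rng = np.random.default_rng(4)
        x = rng.normal(size=64)
        dec = pp.dwt_multilevel(x, spec, 1)
        a, d = pp.dwt_single_level(x, spec)
        np.testing.assert_array_equal(dec.approx, a)
        np.testing.assert_array_equal(dec.details[0], d)

    def test_level_two_equals_repeated_single_level(self):
        spec = pp.get_wavelet("haar", padding="periodic")
        x = np.arange(8.0)
        dec = pp.dwt_multilevel(x, spec, 2)
        a1, d1 = pp.dwt_single_level(x, spec)
        a2, d2 = pp.dwt_single_level(a1, spec)
        np.testing.assert_allclose(dec.approx, a2, atol=1e-12)
        np.testing.assert_allclose(dec.details[0], d1, atol=1e-12)
        np.testing.assert_allclose(dec.details[1], d2, atol=1e-12)

    def test_coefficient_counts_follow_length_recurrence(self):
        # periodic: ceil(n/2) per level -> 256 -> 128 -> 64
        spec = pp.get_wavelet("db4", padding="periodic")
        dec = pp.dwt_multilevel(np.zeros(256), spec, 2)
        assert dec.approx.shape == (64,)
        assert [d.shape[0] for d in dec.details] == [128, 64]

    def test_too_deep_level_raises_with_admissible_maximum(self):
        spec = pp.get_wavelet("db4")
        with pytest.raises(ValueError, match="maximum admissible"):
            pp.dwt_multilevel(np.zeros(64), spec, 5)

    @pytest.mark.parametrize("wavelet", WAVELETS)
    @pytest.mark.parametrize("padding", sorted(PAD_TO_PYWT))
    @pytest.mark.parametrize("n", [64, 100, 256])
    def test_perfect_reconstruction(self, wavelet, padding, n):
        rng = np.random.default_rng(5)
        x = rng.normal(size=n)
        spec = pp.get_wavelet(wavelet, padding=padding)
        max_level = min(4, pp.max_dwt_level(n, spec.filter_length))
        for level in range(1, max_level + 1):
            xr = pp.idwt(pp.dwt_multilevel(x, spec, level))
            assert xr.shape == x.shape
            assert np.max(np.abs(xr - x)) < 1e-8

    def test_multilevel_parseval(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=256)
        spec = pp.get_wavelet("db4", padding="periodic")
        dec = pp.dwt_multilevel(x, spec, 3)
        energy = np.sum(dec.approx**2) + sum(np.sum(d**2) for d in dec.details)
        assert energy == pytest.approx(np.sum(x**2), abs=1e-8)

    def test_zero_coefficients_reconstruct_zero(self):
        spec = pp.get_wavelet("db2")
        dec = pp.dwt_multilevel(np.zeros(64), spec, 2)
        np.testing.assert_allclose(pp.idwt(dec), 0.0, atol=1e-15)

    def test_approx_only_reconstruction_loses_energy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=256)
        spec = pp.get_wavelet("db4", padding="periodic")
        dec = pp.dwt_multilevel(x, spec, 2)
        dec.details = [np.zeros_like(d) for d in dec.details]
        smoothed = pp.idwt(dec)
        assert np.sum(smoothed**2) <= np.sum(x**2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.sampled_from(WAVELETS),
           st.sampled_from(sorted(PAD_TO_PYWT)))
    def test_reconstruction_property_random_signals(self, seed, wavelet, padding):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 200))
        x = rng.normal(size=n) * rng.uniform(0.1, 50)
        spec = pp.get_wavelet(wavelet, padding=padding)
        max_level = pp.max_dwt_level(n, spec.filter_length)
        if max_level < 1:
            return
        level = int(rng.integers(1, max_level + 1))
        xr = pp.idwt(pp.dwt_multilevel(x, spec, level))
        assert np.max(np.abs(xr - x)) < 1e-8


# ---------------------------------------------------------------------------
# Denoising front-end
# ---------------------------------------------------------------------------

class TestDenoiseFeatures:
    def test_db4_symmetric_level2_length_69(self):
        # floor((n + L - 1)/2) applied twice: 256 -> 131 -> 69
        spec = pp.get_wavelet("db4", padding="symmetric")
        out = pp.denoise_features(np.zeros(256), spec, 2)
        assert out.shape == (69,)

    def test_haar_periodic_level2_length_64(self):
        spec = pp.get_wavelet("haar", padding="periodic")
        out = pp.denoise_features(np.zeros(256), spec, 2)
        assert out.shape == (64,)

    @pytest.mark.parametrize("wavelet", WAVELETS)
    @pytest.mark.parametrize("padding", sorted(PAD_TO_PYWT))
    @pytest.mark.parametrize("target", [None, 76])
    def test_feature_length_matches_output(self, wavelet, padding, target):
        rng = np.random.default_rng(8)
        spec = pp.get_wavelet(wavelet, padding=padding)
        x = rng.normal(size=256)
        out = pp.denoise_features(x, spec, 2, target_length=target)
        assert out.shape[-1] == pp.feature_length(256, spec, 2, target_length=target)

    def test_target_length_pads_or_truncates(self):
        spec = pp.get_wavelet("db4", padding="symmetric")
        x = np.random.default_rng(9).normal(size=256)
        natural = pp.denoise_features(x, spec, 2)
        preset = pp.denoise_features(x, spec, 2, target_length=76)
        assert preset.shape == (76,)
        np.testing.assert_array_equal(preset[:69], natural)
        np.testing.assert_array_equal(preset[69:], 0.0)

    def test_rowwise_matches_per_signal(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5, 256))
        spec = pp.get_wavelet("db4")
        batch = pp.denoise_features(X, spec, 2)
        for i in range(5):
            np.testing.assert_allclose(batch[i],
                                       pp.denoise_features(X[i], spec, 2),
                                       atol=1e-12)


def test_unknown_wavelet_raises():
    with pytest.raises(KeyError, match="unknown wavelet"):
        pp.get_wavelet("sym9")


def test_unknown_padding_raises():
    with pytest.raises(ValueError, match="padding"):
        pp.get_wavelet("haar", padding="reflecty")
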
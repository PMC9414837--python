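import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ndoa.errors import DegenerateSignalError, NdoaError
from ndoa.preprocess import (adaptive_threshold, decompose, denoise,
                             denoise_with_config, DenoiseConfig,
                             hard_threshold, permutation_entropy_energy,
                             reconstruct, remove_outliers, soft_threshold,
                             universal_threshold)
from ndoa.synthetic import sinusoid_spike_fixture
from oracles import pe_energy_oracle

finite_arrays = hnp.arrays(
    float, st.integers(8, 64),
    elements=st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False))


class TestRemoveOutliers:
    def test_constant_window_is_noop(self):
        x = np.full(100, 3.5)
        np.testing.assert_array_equal(remove_outliers(x), x)

    def test_single_extreme_sample_clipped_rest_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        x[100] = 10 * x.std()
        out = remove_outliers(x, k=5.0)
        # scalar-loop oracle
        mu, sd = x.mean(), x.std()
        expected = np.array([min(max(v, mu - 5 * sd), mu + 5 * sd)
                             for v in x])
        np.testing.assert_allclose(out, expected)
        assert out[100] != x[100]
        changed = np.nonzero(out != x)[0]
        np.testing.assert_array_equal(changed, [100])

    def test_huge_multiplier_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(64)
        np.testing.assert_array_equal(remove_outliers(x, k=1e9), x)

    def test_empty_window_rejected(self):
        with pytest.raises(NdoaError):
            remove_outliers(np.empty(0))


class TestWaveletTransform:
    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 20, 1280)
        y = reconstruct(decompose(x))
        assert np.max(np.abs(y - x)) / np.max(np.abs(x)) < 1e-8

    def test_zero_signal_gives_zero_coefficients(self):
        dec = decompose(np.zeros(1280))
        for c in dec.coeffs:
            np.testing.assert_array_equal(c, 0.0)

    def test_low_frequency_energy_concentrates_in_approximation(self):
        t = np.arange(1280) / 128.0
        x = 50 * np.sin(2 * np.pi * 1.0 * t)
        dec = decompose(x)
        e_d1 = float(np.sum(dec.details[-1] ** 2))  # finest detail
        e_a = float(np.sum(dec.approximation ** 2))
        assert e_d1 < 1e-3 * e_a

    def test_too_short_signal_rejected(self):
        with pytest.raises(NdoaError):
            decompose(np.ones(8))


class TestUniversalThreshold:
    def test_all_zero_detail(self):
        sigma, th = universal_threshold(np.zeros(100))
        assert sigma == 0.0 and th == 0.0

    def test_known_five_coefficient_example(self):
        # MAD of |1,-2,3,-4,5| is 3; sigma = 3/0.6745; Th = sigma*sqrt(2 ln 5)
        sigma, th = universal_threshold(np.array([1.0, -2.0, 3.0, -4.0, 5.0]))
        assert sigma == pytest.approx(3 / 0.6745, rel=1e-12)
        assert th == pytest.approx((3 / 0.6745) * math.sqrt(2 * math.log(5)),
                                   rel=1e-12)

    @given(finite_arrays, st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_homogeneity_in_scale(self, detail, c):
        _, th = universal_threshold(detail)
        _, th_scaled = universal_threshold(c * detail)
        assert th_scaled == pytest.approx(c * th, rel=1e-9, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(NdoaError):
            universal_threshold(np.empty(0))


class TestPermutationEntropyEnergy:
    def test_monotone_window_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            permutation_entropy_energy(np.arange(100.0), m=3, segments=4)

    def test_single_segment_has_unit_relative_energy(self):
        rng = np.random.default_rng(3)
        _, rpe = permutation_entropy_energy(rng.standard_normal(128), m=3,
                                            segments=1)
        assert rpe == pytest.approx(1.0)

    def test_matches_bruteforce_counter(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=64)
        total, rpe = permutation_entropy_energy(x, m=3, segments=4)
        exp_total, exp_rpe = pe_energy_oracle(x, m=3, segments=4)
        assert total == pytest.approx(exp_total, abs=1e-10)
        assert rpe == pytest.approx(exp_rpe, abs=1e-10)

    def test_segment_shorter_than_dimension_rejected(self):
        with pytest.raises(DegenerateSignalError):
            permutation_entropy_energy(np.arange(20.0), m=3, segments=10)


class TestAdaptiveThreshold:
    def test_unit_relative_energy_gives_a_times_b(self):
        # ln(1) = 0, so Th = |0 - 9| * 6 = 54 regardless of n
        assert adaptive_threshold(1.0, 1280) == pytest.approx(54.0)

    def test_zero_gain_gives_zero(self):
        assert adaptive_threshold(0.3, 1280, b=0.0) == 0.0

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(NdoaError):
            adaptive_threshold(0.0, 1280)

    @given(st.floats(1e-6, 1.0), st.integers(3, 10 ** 6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_always_nonnegative(self, rpe, n):
        assert adaptive_threshold(rpe, n) >= 0.0


class TestShrinkage:
    def test_soft_known_values(self):
        out = soft_threshold(np.array([5.0, -5.0, 1.5, 0.0]), 2.0)
        np.testing.assert_allclose(out, [3.0, -3.0, 0.0, 0.0])

    def test_hard_known_values(self):
        out = hard_threshold(np.array([5.0, -5.0, 1.5, 2.0]), 2.0)
        np.testing.assert_allclose(out, [5.0, -5.0, 0.0, 0.0])

    def test_zero_threshold_is_identity(self):
        c = np.array([3.0, -1.0, 0.5])
        np.testing.assert_array_equal(soft_threshold(c, 0.0), c)
        np.testing.assert_array_equal(hard_threshold(c, 0.0), c)

    @given(finite_arrays, st.floats(0, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_soft_shrinkage_bound_exact(self, c, th):
        out = soft_threshold(c, th)
        assert np.all(np.abs(out) <= np.maximum(np.abs(c) - th, 0.0))

    @given(finite_arrays, st.floats(0, 1e3),
           st.sampled_from([soft_threshold, hard_threshold]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_energy_never_increases(self, c, th, shrink):
        assert np.sum(shrink(c, th) ** 2) <= np.sum(c ** 2)


class TestDenoise:
    def test_zero_signal_stays_zero(self):
        out = denoise(np.zeros(1280))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_threshold_reconstructs_input(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 15, 1280)
        out = denoise(x, threshold_override=0.0)
        assert np.max(np.abs(out - x)) / np.max(np.abs(x)) < 1e-8

    def test_spike_peak_amplitude_reduced(self):
        clean, noisy = sinusoid_spike_fixture(0)
        out = denoise_with_config(noisy, DenoiseConfig())
        assert np.max(np.abs(out)) < np.max(np.abs(noisy))

    def test_output_length_matches_input(self):
        rng = np.random.default_rng(6)
        for n in (640, 1280):
            assert denoise(rng.normal(size=n)).size == n

    def test_unknown_mode_rejected(self):
        with pytest.raises(NdoaError):
            denoise(np.ones(1280), mode="medium")
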
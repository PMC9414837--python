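import math
import time

import numpy as np
import pytest
import scipy.stats

from ndoa.errors import DegenerateSignalError, NdoaError
from ndoa.features import (EntropyParams, PSDFeatureParams, ev_pseudospectrum,
                           extract_features, fuzzy_entropy,
                           hurst_range_response, permutation_entropy_norm,
                           psd_eigenvector_feature, rescaled_range_curve,
                           sample_entropy)
from ndoa.preprocess import remove_outliers
from ndoa.synthetic import StateSchedule, generate
from oracles import (fuzzy_entropy_oracle, hurst_rr_oracle,
                     permutation_entropy_oracle, sample_entropy_oracle)


class TestSampleEntropy:
    def test_alternating_sequence_matches_pair_counting_oracle(self):
        x = [1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        assert sample_entropy(np.array(x)) == pytest.approx(
            sample_entropy_oracle(x), abs=1e-12)

    def test_wide_tolerance_gives_zero(self):
        rng = np.random.default_rng(0)
        x = 5.0 + 1e-6 * rng.standard_normal(50)
        assert sample_entropy(x, r=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(150)
        se = sample_entropy(x)
        assert sample_entropy(3.7 * x + 12.0) == pytest.approx(se, rel=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sample_entropy(np.full(50, 2.0))

    def test_no_extended_matches_signals_infinite_entropy(self):
        # the two (0,0) templates match at length m but their length-m+1
        # extensions (0,0,1) vs (0,0,2) do not -> A = 0 -> inf signalled
        x = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 2.0])
        assert sample_entropy(x, r=0.5) == math.inf

    def test_no_template_matches_at_all_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sample_entropy(np.arange(30.0), r=0.5)


class TestFuzzyEntropy:
    def test_twelve_sample_sequence_matches_membership_oracle(self):
        x = [2.0, 5.0, 1.0, 4.0, 4.5, 0.5, 3.0, 2.5, 6.0, 1.5, 3.5, 2.2]
        assert fuzzy_entropy(np.array(x)) == pytest.approx(
            fuzzy_entropy_oracle(x), abs=1e-10)

    def test_positive_on_iid_noise(self):
        rng = np.random.default_rng(2)
        assert fuzzy_entropy(rng.standard_normal(200)) > 0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(120)
        fe = fuzzy_entropy(x)
        assert fuzzy_entropy(0.2 * x - 7.0) == pytest.approx(fe, rel=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            fuzzy_entropy(np.zeros(50))


class TestPermutationEntropy:
    def test_monotone_sequence_has_zero_entropy(self):
        assert permutation_entropy_norm(np.arange(100.0)) == 0.0

    def test_uniform_pattern_coverage_reaches_one(self):
        # alternating sequence visits both m=2 patterns equally often
        x = np.tile([0.0, 1.0], 25)[:-1]
        assert permutation_entropy_norm(x, m=2) == pytest.approx(1.0)

    def test_seven_sample_example_matches_enumeration_oracle(self):
        x = [4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0]
        assert permutation_entropy_norm(np.array(x), m=3) == pytest.approx(
            permutation_entropy_oracle(x, m=3), abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pe = permutation_entropy_norm(rng.standard_normal(80))
            assert 0.0 <= pe <= 1.0

    def test_too_short_input_rejected(self):
        with pytest.raises(NdoaError):
            permutation_entropy_norm(np.arange(3.0), m=4)


class TestHurstRangeResponse:
    def test_sixteen_sample_sequence_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 3, 16)
        got = hurst_range_response(x, scales=[16, 8])
        assert got == pytest.approx(hurst_rr_oracle(x, [16, 8]), abs=1e-10)

    def test_monotone_ramp_matches_oracle(self):
        x = np.arange(16.0)
        got = hurst_range_response(x, scales=[16, 8])
        assert got == pytest.approx(hurst_rr_oracle(x, [16, 8]), abs=1e-10)

    def test_amplitude_homogeneity(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(256)
        rr = hurst_range_response(x)
        assert hurst_range_response(2.5 * x + 3.0) == pytest.approx(
            2.5 * rr, rel=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            hurst_range_response(np.full(64, 1.0))

    def test_classic_exponent_near_half_for_white_noise(self):
        rng = np.random.default_rng(7)
        h = hurst_range_response(rng.standard_normal(1024), classic=True)
        assert 0.3 < h < 0.75

    def test_curve_exposes_both_range_and_rescaled_range(self):
        rng = np.random.default_rng(8)
        scales, mean_r, mean_rs = rescaled_range_curve(
            rng.standard_normal(128))
        assert scales.size == mean_r.size == mean_rs.size
        assert np.all(mean_r > 0) and np.all(mean_rs > 0)


def _ev_oracle(c, order=12, n_noise=6, n_grid=128):
    """Straight-line eigenvector pseudospectrum evaluation."""
    c = np.asarray(c, float) - np.mean(c)
    n = len(c)
    acf = [sum(c[i] * c[i + k] for i in range(n - k)) / n
           for k in range(order + 1)]
    rmat = np.array([[acf[abs(i - j)] for j in range(order + 1)]
                     for i in range(order + 1)])
    lam, vec = np.linalg.eigh(rmat)
    spec = []
    for g in range(n_grid):
        w = np.pi * g / n_grid
        e = np.exp(-1j * w * np.arange(order + 1))
        denom = 0.0
        for k in range(n_noise):
            denom += abs(np.vdot(vec[:, k], e)) ** 2 / lam[k]
        spec.append(1.0 / denom)
    return np.array(spec)


class TestPSDEigenvectorFeature:
    def test_pseudospectrum_matches_straightline_oracle(self):
        rng = np.random.default_rng(9)
        t = np.arange(200)
        c = (np.sin(0.3 * t) + 0.5 * np.sin(1.1 * t)
             + 0.1 * rng.standard_normal(200))
        got = ev_pseudospectrum(c)
        np.testing.assert_allclose(got, _ev_oracle(c), rtol=1e-8)

    def test_two_tone_window_feature_matches_recomputation(self):
        t = np.arange(1280) / 128.0
        x = 20 * np.sin(2 * np.pi * 2 * t) + 5 * np.sin(2 * np.pi * 11 * t)
        a = psd_eigenvector_feature(x)
        b = psd_eigenvector_feature(x.copy())
        assert a == b  # deterministic pure function
        assert np.isfinite(a)

    def test_amplitude_scaling_shifts_feature_additively(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 10, 1280)
        p = PSDFeatureParams()
        f1 = psd_eigenvector_feature(x, p)
        f2 = psd_eigenvector_feature(4.0 * x, p)
        # pseudospectra scale by c^2, so both log terms shift by 2 ln c
        expected_shift = (p.k1 + p.k2) / p.k3 * 2 * math.log(4.0)
        assert f2 - f1 == pytest.approx(expected_shift, rel=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(NdoaError):
            ev_pseudospectrum(np.arange(10.0))


class TestExtractFeatures:
    def test_constant_window_flagged_degenerate(self):
        fv = extract_features(np.full(1280, 5.0))
        assert fv.degenerate

    def test_feature_vector_is_reproducible(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 10, 1280)
        a = extract_features(x).as_array()
        b = extract_features(x.copy()).as_array()
        np.testing.assert_array_equal(a, b)

    def test_single_window_extraction_is_realtime_feasible(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 10, 1280)
        t0 = time.perf_counter()
        extract_features(x)
        assert time.perf_counter() - t0 < 1.0

    def test_entropies_separate_awake_from_deep_windows(self):
        """Awake-like (broadband, low-voltage) windows carry higher SE, FE
        and PE than deep-like (slow, high-voltage) windows.

        The check runs on the state-fixture windows after outlier clipping
        only: the wavelet threshold's absolute scale (tens of µV) sits above
        the awake-state amplitude, so post-threshold residues no longer
        carry the states' irregularity contrast — the ordering is a property
        of the signals the generator emits.
        """
        awake = generate(StateSchedule([("awake", 70)]), seed=21)
        deep = generate(StateSchedule([("deep", 70)]), seed=22)
        feats = {}
        for name, log in (("awake", awake), ("deep", deep)):
            rows = []
            for t in range(0, 60):
                w = log.recording.samples[t * 128:(t + 10) * 128]
                fv = extract_features(remove_outliers(w))
                assert not fv.degenerate
                rows.append(fv.as_array())
            feats[name] = np.array(rows)
        for j, fname in enumerate(("se", "fe", "pe")):
            stat = scipy.stats.mannwhitneyu(feats["awake"][:, j],
                                            feats["deep"][:, j],
                                            alternative="greater")
            assert stat.pvalue < 1e-6, fname
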
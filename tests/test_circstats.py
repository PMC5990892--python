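import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canolux.circstats import (angular_difference, circ_mean,
                               circular_dispersion, rao_homogeneity,
                               rayleigh_test, resultant_length,
                               sample_vonmises, summarize, vonmises_A,
                               vonmises_kappa)
from canolux.circstats import test_specified_mean as specified_mean_test


class TestCircMean:
    @pytest.mark.parametrize("angles, expected", [
        ([10.0, 350.0], 0.0),
        ([180.0], 180.0),
        ([90.0, 90.0, 270.0], 90.0),
    ])
    def test_examples(self, angles, expected):
        assert abs(angular_difference(circ_mean(angles), expected)) < 1e-9

    def test_antipodal_pair_undefined(self):
        assert math.isnan(circ_mean([0.0, 180.0]))

    @given(st.lists(st.floats(0, 360, exclude_max=True), min_size=3,
                    max_size=20),
           st.floats(-180, 180))
    def test_rotation_equivariance(self, angles, shift):
        base = circ_mean(angles)
        if math.isnan(base) or resultant_length(angles) < 1e-3:
            return
        rotated = circ_mean([(a + shift) % 360 for a in angles])
        assert abs(angular_difference(rotated, (base + shift) % 360)) < 1e-6
        assert resultant_length([(a + shift) % 360 for a in angles]) \
            == pytest.approx(resultant_length(angles), abs=1e-9)


class TestKappa:
    def test_A_inverse_identity(self):
        for r in np.linspace(0.01, 0.99, 25):
            assert vonmises_A(vonmises_kappa(r)) == pytest.approx(r,
                                                                  abs=1e-6)

    def test_limits(self):
        assert vonmises_kappa(0.0) == 0.0
        assert math.isinf(vonmises_kappa(1.0))


class TestSummarize:
    def test_uniform_sample_has_no_concentration(self):
        angles = sample_vonmises(1000, 0.0, 0.0, seed=0)
        s = summarize(angles)
        assert s.rbar < 0.1
        assert s.kappa_vm < 0.25

    def test_vonmises_parameter_recovery(self):
        angles = sample_vonmises(500, 180.0, 2.0, seed=1)
        s = summarize(angles)
        assert abs(angular_difference(s.mu, 180.0)) < 5.0
        assert 1.6 <= s.kappa_vm <= 2.4

    def test_point_mass_degenerate(self):
        s = summarize([77.0] * 10)
        assert s.rbar == pytest.approx(1.0)
        assert s.dispersion == 0.0
        assert math.isinf(s.kappa_vm)

    def test_dispersion_approximates_inverse_kappa(self):
        angles = sample_vonmises(5000, 90.0, 10.0, seed=2)
        d = circular_dispersion(angles)
        assert d == pytest.approx(0.1, rel=0.15)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize([10.0])


class TestSampler:
    def test_deterministic_under_seed(self):
        a = sample_vonmises(100, 45.0, 3.0, seed=7)
        b = sample_vonmises(100, 45.0, 3.0, seed=7)
        assert np.array_equal(a, b)

    def test_uniform_limit_passes_rayleigh(self):
        rng = np.random.default_rng(3)
        ok = 0
        for _ in range(30):
            _, p = rayleigh_test(sample_vonmises(10_000, 0.0, 0.0, rng))
            ok += p > 0.01
        assert ok >= 28

    def test_high_concentration_is_tight(self):
        angles = sample_vonmises(2000, 200.0, 50.0, seed=4)
        circ_sd = math.degrees(math.sqrt(
            -2.0 * math.log(resultant_length(angles))))
        assert circ_sd < 10.0

    def test_matches_numpy_reference_sampler(self):
        """Two-sample KS between our Best-Fisher draws and numpy's von
        Mises generator (independent route)."""
        from scipy import stats

        rng = np.random.default_rng(5)
        ours = sample_vonmises(4000, 180.0, 3.0, rng)
        ref = (np.degrees(rng.vonmises(math.radians(180.0) - math.pi, 3.0,
                                       4000)) + 180.0) % 360.0
        # both centred at 180 so the 0/360 cut does not split the mode
        _, p = stats.ks_2samp(ours, ref)
        assert p > 0.001

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_vonmises(0, 0.0, 1.0)
        with pytest.raises(ValueError):
            sample_vonmises(10, 0.0, -1.0)


class TestSpecifiedMean:
    def test_level_true_mean_rarely_rejected(self):
        rng = np.random.default_rng(6)
        not_rejected = 0
        for _ in range(100):
            angles = sample_vonmises(100, 180.0, 2.0, rng)
            res = specified_mean_test(angles, 180.0, B=999, seed=rng)
            not_rejected += res.pvalue > 0.05
        assert not_rejected >= 90

    def test_power_opposite_direction_always_rejected(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(100):
            angles = sample_vonmises(100, 180.0, 2.0, rng)
            res = specified_mean_test(angles, 0.0, B=999, seed=rng)
            rejections += res.rejected
        assert rejections >= 99

    def test_ci_contains_sample_mean(self):
        angles = sample_vonmises(80, 10.0, 3.0, seed=8)
        res = specified_mean_test(angles, 0.0, B=999, seed=9)
        lo = angular_difference(res.ci_lo, res.mu_hat)
        hi = angular_difference(res.ci_hi, res.mu_hat)
        assert lo < 0 < hi

    def test_bootstrap_ci_coverage(self):
        """Nominal 95% CI covers the true mean 92-98% of the time."""
        rng = np.random.default_rng(10)
        covered = 0
        reps = 500
        for _ in range(reps):
            angles = sample_vonmises(50, 180.0, 2.0, rng)
            res = specified_mean_test(angles, 180.0, B=999, seed=rng)
            covered += not res.rejected
        assert 0.92 <= covered / reps <= 0.98

    def test_invalid_arguments(self):
        angles = sample_vonmises(50, 0.0, 2.0, seed=11)
        with pytest.raises(ValueError):
            specified_mean_test(angles, 0.0, B=0)
        with pytest.raises(ValueError):
            specified_mean_test(angles[:5], 0.0)

    def test_uniform_sample_not_applicable(self):
        rng = np.random.default_rng(12)
        angles = np.linspace(0, 360, 36, endpoint=False)
        res = specified_mean_test(angles, 0.0, B=99, seed=rng)
        assert not res.applicable


class TestRaoHomogeneity:
    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(13)
        rej_means = rej_disp = 0
        reps = 200
        for _ in range(reps):
            samples = [sample_vonmises(90, 180.0, 2.0, rng)
                       for _ in range(5)]
            res = rao_homogeneity(samples)
            rej_means += res.p_means < 0.05
            rej_disp += res.p_disp < 0.05
        assert rej_means / reps <= 0.10
        assert rej_disp / reps <= 0.10

    def test_detects_dispersion_shift(self):
        """One diffuse sector among concentrated ones (the field study's
        west-sector pattern)."""
        rng = np.random.default_rng(14)
        hits = 0
        reps = 100
        for _ in range(reps):
            samples = [sample_vonmises(90, 180.0, 2.0, rng)
                       for _ in range(4)]
            samples.append(sample_vonmises(90, 180.0, 0.3, rng))
            hits += rao_homogeneity(samples).p_disp < 0.05
        assert hits / reps >= 0.80

    def test_detects_mean_shift(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(50):
            samples = [sample_vonmises(90, 180.0, 2.0, rng)
                       for _ in range(4)]
            samples.append(sample_vonmises(90, 120.0, 2.0, rng))
            hits += rao_homogeneity(samples).p_means < 0.05
        assert hits >= 45

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rao_homogeneity([sample_vonmises(50, 0.0, 2.0, seed=16)])
        with pytest.raises(ValueError):
            rao_homogeneity([[1.0] * 5, [2.0] * 5])

    def test_degenerate_sample_not_applicable(self):
        rng = np.random.default_rng(17)
        samples = [sample_vonmises(90, 180.0, 2.0, rng) for _ in range(4)]
        samples.append(np.linspace(0, 360, 90, endpoint=False))  # uniform
        assert not rao_homogeneity(samples).applicable
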
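import numpy as np
import pytest
from scipy import stats

from iedwaves import (bimodality_index, circular_median, circular_median_test,
                      fit_vmm, hermans_rasson_test, kld_directions,
                      kld_permutation_test, kuiper_statistic, sample_vmm,
                      watson_williams)
from iedwaves.circular import (angle_difference, circular_sd,
                               hermans_rasson_statistic, resultant_length)
from iedwaves.synthetic import DirectionModel

UNIMODAL = DirectionModel(mu=(0.0,), kappa=(2.0,), weights=(1.0,))
ANTIPODAL = DirectionModel(mu=(0.0, np.pi), kappa=(3.0, 3.0), weights=(0.5, 0.5))


class TestHermansRasson:
    def test_concentrated_sample_rejected(self):
        a = sample_vmm(UNIMODAL, 200, seed=3)
        assert hermans_rasson_test(a, seed=4) <= 0.001

    def test_uniform_grid_not_rejected(self):
        a = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        assert hermans_rasson_test(a, seed=5) > 0.5

    def test_antipodal_power_where_rayleigh_fails(self):
        # resultant vector ~0, yet HR retains power against axial bimodality
        a = sample_vmm(ANTIPODAL, 200, seed=6)
        assert resultant_length(a) < 0.15
        assert hermans_rasson_test(a, seed=7) < 0.05

    def test_rotation_invariance_of_statistic(self):
        a = sample_vmm(UNIMODAL, 50, seed=8)
        t0 = hermans_rasson_statistic(a)
        t1 = hermans_rasson_statistic((a + 1.234) % (2 * np.pi))
        assert t0 == pytest.approx(t1, rel=1e-9)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            hermans_rasson_test([0.1, 0.2, 0.3])


class TestVonMisesMixture:
    def test_degenerate_point_mass_caps_kappa(self):
        fit = fit_vmm(np.full(50, 1.0), h=1, seed=0)
        assert fit.mu_h[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.kappa_h[0] == pytest.approx(1e3)

    def test_two_component_recovery(self):
        dm = DirectionModel(mu=(0.0, np.pi), kappa=(4.0, 4.0), weights=(0.7, 0.3))
        a = sample_vmm(dm, 2000, seed=1)
        fit = fit_vmm(a, h=2, seed=2)
        assert fit.theta_h[0] == pytest.approx(0.7, abs=0.05)
        assert angle_difference(fit.mu_h[0], 0.0) < 0.1
        assert angle_difference(fit.mu_h[1], np.pi) < 0.1
        assert abs(sum(fit.theta_h) - 1.0) < 1e-9
        assert all(k >= 0 for k in fit.kappa_h)

    def test_reported_separation_recovered(self):
        dm = DirectionModel.antipodal(mu_deg=120.0, separation_deg=177.9,
                                      kappa=4.0, dominant_weight=0.7)
        seps = []
        for s in range(10):
            a = sample_vmm(dm, 1000, seed=s)
            fit = fit_vmm(a, h=2, seed=s)
            seps.append(np.rad2deg(angle_difference(fit.mu_h[0], fit.mu_h[1])))
        assert abs(np.mean(seps) - 177.9) < 5.0

    def test_h2_likelihood_at_least_h1(self):
        a = sample_vmm(UNIMODAL, 300, seed=9)
        ll1 = fit_vmm(a, h=1, seed=0).log_likelihood
        ll2 = fit_vmm(a, h=2, seed=0).log_likelihood
        assert ll2 >= ll1 - 1e-6

    def test_too_few_angles_raises(self):
        with pytest.raises(ValueError):
            fit_vmm(np.zeros(15), h=2)


class TestKuiper:
    def test_quantile_grid_gives_one_over_n(self):
        n = 20
        u = (np.arange(1, n + 1) - 0.5) / n
        angles = (stats.vonmises.ppf(u, 2.0) + 1.0) % (2 * np.pi)
        assert kuiper_statistic(angles, 1.0, 2.0) == pytest.approx(1 / n, abs=1e-9)

    def test_rotation_invariance_uniform_model(self, rng):
        a = rng.uniform(0, 2 * np.pi, 40)
        v0 = kuiper_statistic(a, 0.0, 0.0)
        v1 = kuiper_statistic((a + 2.5) % (2 * np.pi), 0.0, 0.0)
        assert v0 == pytest.approx(v1, abs=1e-12)

    def test_point_mass_far_from_concentrated_model(self):
        v = kuiper_statistic(np.full(30, np.pi), 0.0, 50.0)
        assert v > 0.99


class TestBimodality:
    def test_antipodal_positive_index(self):
        dm = DirectionModel(mu=(0.0, np.pi), kappa=(3.0, 3.0), weights=(0.6, 0.4))
        hits = 0
        for s in range(5):
            a = sample_vmm(dm, 1000, seed=s)
            if bimodality_index(a, seed=s)["index"] > 0:
                hits += 1
        assert hits >= 4

    def test_unimodal_negative_index(self):
        dm = DirectionModel(mu=(0.0,), kappa=(3.0,), weights=(1.0,))
        hits = 0
        for s in range(5):
            a = sample_vmm(dm, 1000, seed=100 + s)
            if bimodality_index(a, seed=s)["index"] < 0:
                hits += 1
        assert hits >= 4

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            bimodality_index(np.zeros(59))


class TestMultiSample:
    def test_watson_williams_separated_means(self):
        a = sample_vmm(DirectionModel(mu=(0.0,), kappa=(5.0,), weights=(1.0,)),
                       100, seed=0)
        b = sample_vmm(DirectionModel(mu=(np.pi / 2,), kappa=(5.0,), weights=(1.0,)),
                       100, seed=1)
        assert watson_williams([a, b])["p"] < 0.001

    def test_watson_williams_same_mean_not_rejected(self):
        a = sample_vmm(DirectionModel(mu=(1.0,), kappa=(3.0,), weights=(1.0,)),
                       80, seed=2)
        b = sample_vmm(DirectionModel(mu=(1.0,), kappa=(3.0,), weights=(1.0,)),
                       80, seed=3)
        assert watson_williams([a, b])["p"] > 0.01

    def test_median_test_identical_groups(self):
        a = sample_vmm(UNIMODAL, 50, seed=4)
        p = circular_median_test(a, a.copy(), n_perm=200, seed=5)
        assert p > 0.5

    def test_median_test_tiny_group_raises(self):
        with pytest.raises(ValueError):
            circular_median_test([0.1] * 3, [0.2] * 50)


class TestKLD:
    def test_identical_samples_zero(self, rng):
        a = rng.uniform(0, 2 * np.pi, 200)
        assert kld_directions(a, a) == 0.0
        assert kld_directions(a, a, pseudocount=0) == 0.0

    def test_point_mass_vs_uniform_closed_form(self):
        p = np.full(100, 0.1)
        q = np.linspace(0, 2 * np.pi, 18, endpoint=False) + 0.01
        kld = kld_directions(p, q, pseudocount=0)
        assert kld == pytest.approx(np.log2(18), abs=1e-9)

    def test_nonnegative(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 2 * np.pi, 50)
            b = rng.uniform(0, 2 * np.pi, 70)
            assert kld_directions(a, b) >= 0.0

    def test_permutation_detects_distinct_distributions(self):
        a = sample_vmm(DirectionModel(mu=(0.0,), kappa=(4.0,), weights=(1.0,)),
                       300, seed=0)
        b = sample_vmm(DirectionModel(mu=(np.pi,), kappa=(4.0,), weights=(1.0,)),
                       300, seed=1)
        out = kld_permutation_test(a, b, n_perm=200, seed=2)
        assert out["p"] <= 0.01

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kld_permutation_test([], [0.1])


class TestDescriptive:
    def test_circular_median_concentrated(self):
        a = sample_vmm(DirectionModel(mu=(2.0,), kappa=(20.0,), weights=(1.0,)),
                       501, seed=0)
        assert angle_difference(circular_median(a), 2.0) < 0.1

    def test_circular_sd_matches_definition(self):
        a = np.array([0.0, 0.1, -0.1, 0.2, -0.2])
        r = resultant_length(a)
        assert circular_sd(a) == pytest.approx(np.sqrt(-2 * np.log(r)))

    def test_bessel_ratio_inversion_roundtrip(self):
        from iedwaves.circular import _a1, _a1_inv
        for kappa in (0.1, 1.0, 2.0, 10.0, 100.0):
            assert _a1_inv(float(_a1(kappa))) == pytest.approx(kappa, rel=1e-6)
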
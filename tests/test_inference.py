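"""Quadrature, likelihood surface, optimization, SEs, EB prediction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mtplong.inference import (
    FitOptions,
    QuadratureConfig,
    _Transform,
    compute_standard_errors,
    fd_hessian,
    fit_model,
    information_criteria,
    marginal_subject_loglik,
    predict_random_effects,
    total_negloglik,
)
from mtplong.model import (
    ModelSpec,
    PanelDataset,
    ParameterVector,
    RandomEffectsCov,
    subject_log_integrand,
)
from _oracles import brute_force_subject_loglik

SPEC_MTP = ModelSpec("mtp", "gamma")
SPEC_TPC = ModelSpec("tp_correlated", "gamma")


class TestMarginalSubjectLoglik:
    def test_degenerate_equals_integrand_at_zero(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        pv = ParameterVector(toy_params.cont_coef, toy_params.k, toy_params.sigma,
                             RandomEffectsCov(0, 0, 0), alpha=toy_params.alpha)
        sl = ds.subject_slice(3)
        got = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], pv, SPEC_MTP)
        ref = subject_log_integrand(ds.y[sl], ds.Z[sl], ds.X[sl], pv, SPEC_MTP, (0, 0))
        assert got == pytest.approx(ref, rel=1e-12)

    def test_symmetric_logistic_integral(self):
        # single y = 0 record, z'alpha = 0, var1 = 1:
        # E_{u~N(0,1)}[1 - expit(u)] = 1/2 by symmetry of expit
        pv = ParameterVector(np.array([0.0]), 1.0, 1.0,
                             RandomEffectsCov(1.0, 0.0, 0.0), alpha=np.array([0.0]))
        got = marginal_subject_loglik([0.0], [[1.0]], [[1.0]], pv, SPEC_MTP)
        assert got == pytest.approx(np.log(0.5), abs=1e-5)

    @pytest.mark.parametrize("spec", [SPEC_MTP, SPEC_TPC])
    def test_against_brute_force(self, spec, toy_params, five_subject_panel):
        ds = five_subject_panel
        quad = QuadratureConfig()
        for i in range(ds.n_subjects):
            sl = ds.subject_slice(i)
            got = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, spec, quad)
            ref = brute_force_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, spec)
            assert got == pytest.approx(ref, rel=1e-4)

    def test_node_count_stability(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        sl = ds.subject_slice(0)
        l7 = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, SPEC_MTP,
                                     QuadratureConfig(nodes_per_dim=7))
        l15 = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, SPEC_MTP,
                                      QuadratureConfig(nodes_per_dim=15))
        assert abs(l7 - l15) / abs(l15) < 1e-5

    def test_adaptive_beats_nonadaptive(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        sl = ds.subject_slice(3)
        ref = brute_force_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, SPEC_MTP)
        ada = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, SPEC_MTP,
                                      QuadratureConfig(nodes_per_dim=7, adaptive=True))
        non = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], toy_params, SPEC_MTP,
                                      QuadratureConfig(nodes_per_dim=7, adaptive=False))
        assert abs(ada - ref) < abs(non - ref)


class TestTotalNegloglik:
    def _theta(self, toy_params):
        tr = _Transform("joint", "gamma", 2, 2)
        return tr.pack(toy_params)

    def test_duplication_doubles(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        theta = self._theta(toy_params)
        base = total_negloglik(theta, ds, SPEC_MTP)
        dup = PanelDataset(
            subject=np.concatenate([ds.subj_index, ds.subj_index + 100]),
            time=np.tile(ds.time, 2), y=np.tile(ds.y, 2),
            Z=np.vstack([ds.Z, ds.Z]), X=np.vstack([ds.X, ds.X]),
        )
        assert total_negloglik(theta, dup, SPEC_MTP) == pytest.approx(2 * base, rel=1e-10)

    def test_reorder_invariance(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        theta = self._theta(toy_params)
        base = total_negloglik(theta, ds, SPEC_MTP)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_records)
        shuffled = PanelDataset(
            subject=ds.subj_index[perm], time=ds.time[perm], y=ds.y[perm],
            Z=ds.Z[perm], X=ds.X[perm],
        )
        assert total_negloglik(theta, shuffled, SPEC_MTP) == pytest.approx(base, rel=1e-10)

    def test_against_brute_force_sum(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        theta = self._theta(toy_params)
        got = -total_negloglik(theta, ds, SPEC_MTP)
        ref = sum(
            brute_force_subject_loglik(ds.y[ds.subject_slice(i)], ds.Z[ds.subject_slice(i)],
                                       ds.X[ds.subject_slice(i)], toy_params, SPEC_MTP)
            for i in range(ds.n_subjects)
        )
        assert got == pytest.approx(ref, rel=1e-4)

    def test_tp_separability(self, toy_params, five_subject_panel):
        # with cov12 = 0 the joint TP likelihood equals the sum of the two
        # separately evaluated one-random-effect parts
        ds = five_subject_panel
        pv0 = ParameterVector(toy_params.cont_coef, toy_params.k, toy_params.sigma,
                              RandomEffectsCov(0.6, 0.4, 0.0), alpha=toy_params.alpha)
        theta_joint = _Transform("joint", "gamma", 2, 2).pack(pv0)
        tb = _Transform("binary", "gamma", 2, 0)
        tc = _Transform("cont", "gamma", 0, 2)
        theta_sep = np.concatenate([tb.pack(pv0), tc.pack(pv0)])
        joint = total_negloglik(theta_joint, ds, SPEC_TPC)
        sep = total_negloglik(theta_sep, ds, ModelSpec("tp_uncorrelated", "gamma"))
        assert joint == pytest.approx(sep, rel=1e-8)

    def test_one_part_brute_force(self, five_subject_panel):
        # 1-D analogue: one-part marginal vs trapezoid integration over u0
        from mtplong.ggfamily import GGParams, gg_log_density

        ds = five_subject_panel
        coef = np.array([0.2, 0.1])
        k = sigma = 0.8
        var0 = 0.3
        pv = ParameterVector(coef, k, sigma, RandomEffectsCov(0, var0, 0, False), None)
        theta = _Transform("one_part", "gamma", 0, 2).pack(pv)
        spec = ModelSpec("one_part", "gamma")
        got = -total_negloglik(theta, ds, spec)

        c = 0.5 * ds.y[ds.y > 0].min()
        y_adj = np.where(ds.y == 0, c, ds.y)
        u = np.linspace(-8 * np.sqrt(var0), 8 * np.sqrt(var0), 4001)
        prior = np.exp(-0.5 * u**2 / var0) / np.sqrt(2 * np.pi * var0)
        ref = 0.0
        for i in range(ds.n_subjects):
            sl = ds.subject_slice(i)
            ll_u = np.zeros_like(u)
            for yy, ww in zip(y_adj[sl], ds.W[sl]):
                mu = ww @ coef + u
                ll_u += np.array([gg_log_density(yy, GGParams(k, sigma, m)) for m in mu])
            ref += np.log(np.trapezoid(np.exp(ll_u) * prior, u))
        assert got == pytest.approx(ref, rel=1e-5)


class TestStandardErrors:
    def test_unit_curvature(self):
        # negloglik = 0.5 (theta - 3)^2 -> information 1 -> SE 1
        H = fd_hessian(lambda x: 0.5 * (x[0] - 3.0) ** 2, np.array([3.0]))
        se, vcov, ok = compute_standard_errors(H)
        assert ok and se[0] == pytest.approx(1.0, rel=1e-6)

    def test_logistic_glm_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        eta = X @ np.array([0.3, -0.8])
        yb = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

        def negll(beta):
            lp = X @ beta
            return float(np.sum(np.logaddexp(0, lp) - yb * lp))

        res = minimize(negll, np.zeros(2), method="BFGS")
        H = fd_hessian(negll, res.x)
        se, _, ok = compute_standard_errors(H)
        ref = sm.Logit(yb, X).fit(disp=0)
        assert ok
        np.testing.assert_allclose(res.x, ref.params, atol=1e-4)
        np.testing.assert_allclose(se, ref.bse, atol=1e-4)

    def test_indefinite_hessian_flagged(self):
        se, vcov, ok = compute_standard_errors(np.array([[1.0, 0.0], [0.0, -2.0]]))
        assert not ok


class TestInformationCriteria:
    def test_printed_fit_statistics_row(self):
        # -2logLik 5795.6, p = 16, n = 693 subjects
        aic, bic, neg2 = information_criteria(-5795.6 / 2, 16, 693)
        assert aic == pytest.approx(5827.6, abs=1e-9)
        assert neg2 == pytest.approx(5795.6, abs=1e-9)
        # printed BIC 5900.2; recomputation agrees to rounding of -2logLik
        assert bic == pytest.approx(5900.2, abs=0.1)

    def test_zero_params(self):
        aic, bic, neg2 = information_criteria(-10.0, 0, 50)
        assert aic == bic == neg2 == 20.0

    def test_fit_result_invariants(self, small_mtp_fit):
        _, _, fit = small_mtp_fit
        assert fit.aic - fit.neg2loglik == pytest.approx(2 * fit.n_params, rel=1e-12)
        assert fit.bic - fit.neg2loglik == pytest.approx(
            fit.n_params * np.log(fit.n_subjects), rel=1e-12)


class TestFitModel:
    def test_two_part_needs_zeros_and_positives(self):
        ds = PanelDataset([0, 1], [0, 0], [1.0, 2.0], np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(ValueError, match="zero and positive"):
            fit_model(ds, SPEC_MTP)

    def test_small_fit_recovers_and_reports(self, small_mtp_fit):
        cfg, data, fit = small_mtp_fit
        assert fit.converged
        assert fit.n_params == 10
        tv = np.concatenate([cfg.truth.alpha, cfg.truth.cont_coef])
        est, se = fit.natural[:6], fit.se[:6]
        assert np.all(np.isfinite(se))
        # small n: allow 3 SE
        assert np.all(np.abs(est - tv) < 3 * se)

    def test_covariate_rescaling_invariance(self):
        from mtplong.simulate import default_study_config, simulate_panel

        cfg = default_study_config(zero_prop=0.3, n_subjects=80, n_visits=3, seed=23)
        ds = simulate_panel(cfg, np.random.default_rng(23))
        opts = FitOptions(pre_fit=False, compute_se=False)
        f1 = fit_model(ds, cfg.spec, options=opts)
        c = 10.0
        X2 = ds.X.copy()
        X2[:, 2] *= c
        Z2 = ds.Z.copy()
        Z2[:, 2] *= c
        ds2 = PanelDataset(ds.subj_index, ds.time, ds.y, Z2, X2)
        f2 = fit_model(ds2, cfg.spec, options=opts)
        assert f2.loglik == pytest.approx(f1.loglik, abs=5e-3)
        assert f2.estimates.cont_coef[2] == pytest.approx(f1.estimates.cont_coef[2] / c, rel=2e-2)
        assert f2.estimates.alpha[2] == pytest.approx(f1.estimates.alpha[2] / c, rel=2e-2)

    def test_free_correlation_no_worse_than_fixed_zero(self):
        from mtplong.simulate import default_study_config, simulate_panel

        cfg = default_study_config(zero_prop=0.3, n_subjects=60, n_visits=3, seed=29)
        ds = simulate_panel(cfg, np.random.default_rng(29))
        free = fit_model(ds, cfg.spec, options=FitOptions(pre_fit=False, compute_se=False))
        # optimize with the atanh-correlation entry pinned at 0
        p_full = len(free.theta)

        def negll_fixed(th_red):
            th = np.concatenate([th_red, [0.0]])
            return total_negloglik(th, ds, cfg.spec)

        res = minimize(negll_fixed, free.theta[: p_full - 1], method="BFGS",
                       options={"maxiter": 300})
        assert free.loglik >= -res.fun - 1e-6


class TestPredictRandomEffects:
    def test_modes_match_grid_refined_oracle(self, small_mtp_fit):
        from scipy.stats import multivariate_normal

        cfg, data, fit = small_mtp_fit
        eb = predict_random_effects(data, fit)
        pv = fit.estimates
        G = pv.re_cov.matrix()
        mvn = multivariate_normal(mean=[0, 0], cov=G)
        for i in range(5):
            sl = data.subject_slice(i)

            def negpost(u):
                return -(subject_log_integrand(data.y[sl], data.Z[sl], data.X[sl],
                                               pv, cfg.spec, u) + mvn.logpdf(u))

            ref = minimize(negpost, np.zeros(2), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12}).x
            np.testing.assert_allclose(eb[i], ref, atol=1e-3)

    def test_high_outcome_subject_has_positive_u2(self, small_mtp_fit):
        cfg, data, fit = small_mtp_fit
        p_z, p_x = data.Z.shape[1], data.X.shape[1]
        big = np.array([30.0, 40.0, 35.0])
        small = np.array([0.0, 0.05, 0.1])
        ds = PanelDataset(
            subject=[0, 0, 0, 1, 1, 1], time=np.arange(6, dtype=float),
            y=np.concatenate([big, small]),
            Z=np.tile(np.eye(1, p_z).ravel(), (6, 1)),
            X=np.tile(np.eye(1, p_x).ravel(), (6, 1)),
        )
        eb = predict_random_effects(ds, fit)
        assert eb[0, 1] > 0
        assert eb[0, 1] > eb[1, 1]
        # shrinkage: a single-record subject sits closer to 0 than a
        # three-record subject with the same outcome value
        ds1 = PanelDataset([0], [0.0], [30.0],
                           np.eye(1, p_z), np.eye(1, p_x))
        eb1 = predict_random_effects(ds1, fit)
        assert 0 < eb1[0, 1] < eb[0, 1]
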
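"""Panel container and per-observation likelihood building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtplong.ggfamily import GGParams, gg_sample, offset_C
from mtplong.model import (
    ModelSpec,
    PanelDataset,
    ParameterVector,
    RandomEffectsCov,
    classify_zero,
    mtp_location,
    one_part_location,
    subject_integrand,
    subject_log_integrand,
    tp_conditional_location,
    tp_marginal_mean,
    zero_part_prob,
)

SPEC_MTP = ModelSpec("mtp", "gamma")
SPEC_TP = ModelSpec("tp_correlated", "gamma")


class TestPanelDataset:
    def test_grouping_and_order(self):
        ds = PanelDataset(
            subject=["b", "a", "b", "a"], time=[0, 0, 1, 1],
            y=[0.0, 1.0, 2.0, 0.0],
            Z=np.ones((4, 1)), X=np.ones((4, 1)),
        )
        assert ds.n_subjects == 2
        assert list(ds.subject_ids) == ["b", "a"]  # order of first appearance
        assert ds.n_records == 4
        np.testing.assert_array_equal(ds.subj_index, [0, 0, 1, 1])

    def test_negative_outcome_rejected(self):
        with pytest.raises(ValueError, match="offending record"):
            PanelDataset([1], [0.0], [-0.5], np.ones((1, 1)), np.ones((1, 1)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            PanelDataset([1, 2], [0.0], [1.0], np.ones((1, 1)), np.ones((1, 1)))


class TestClassifyZero:
    @pytest.mark.parametrize("y,thr,expect", [
        (0.0, 0.0, 0), (3.2, 0.0, 1), (0.01, 0.05, 0), (0.06, 0.05, 1),
    ])
    def test_threshold_semantics(self, y, thr, expect):
        assert classify_zero(y, ModelSpec("mtp", "gamma", zero_threshold=thr)) == expect

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_zero(-0.1, SPEC_MTP)


class TestZeroPartProb:
    def test_center(self):
        assert zero_part_prob([1.0], [0.0], 0.0) == pytest.approx(0.5)

    def test_log_odds(self):
        assert zero_part_prob([1.0], [np.log(3.0)], 0.0) == pytest.approx(0.75)

    def test_extreme_stability(self):
        p = zero_part_prob([1.0], [0.0], -50.0)
        assert 0 < p < 1e-20

    def test_dimension_error(self):
        with pytest.raises(ValueError):
            zero_part_prob([1.0, 2.0], [0.5], 0.0)

    @given(st.floats(-5, 5), st.floats(0.1, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_alpha(self, a, dz):
        # raising a coefficient with positive covariate value raises pi
        lo = zero_part_prob([1.0, dz], [0.0, a], 0.0)
        hi = zero_part_prob([1.0, dz], [0.0, a + 0.5], 0.0)
        assert hi > lo


class TestLocations:
    def test_tp_additivity(self):
        assert tp_conditional_location([1.0], [0.0], 0.0) == 0.0
        assert tp_conditional_location([1.0], [1.3], -0.3) == pytest.approx(1.0)

    def test_tp_conditional_mean_monte_carlo(self):
        mu = tp_conditional_location([1.0, 2.0], [0.1, 0.2], 0.1)  # = 0.6
        p = GGParams(0.6, 0.6, float(mu))
        s = gg_sample(p, 100_000, np.random.default_rng(9))
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - np.exp(mu + offset_C(0.6, 0.6))) < 4 * se

    def test_mtp_trivials(self):
        assert mtp_location([1.0], [0.0], 0.0, 1.0, 0.0) == 0.0
        assert mtp_location([1.0], [1.0], 0.0, 0.5, 0.0) == pytest.approx(1.0 + np.log(2.0))

    def test_mtp_pi_domain(self):
        with pytest.raises(ValueError):
            mtp_location([1.0], [1.0], 0.0, 0.0, 0.0)

    def test_one_part_location(self):
        assert one_part_location([1.0, 2.0], [0.5, 0.25], 0.0) == pytest.approx(1.0)

    @given(st.floats(-3, 3), st.floats(-2, 2), st.floats(0.01, 1.0),
           st.floats(-1, 1))
    @settings(max_examples=200, deadline=None)
    def test_marginal_mean_round_trip(self, xb, u2, pi, C):
        # pi * exp(mu + C) == exp(x'beta + u2) to machine precision
        mu = mtp_location([1.0], [xb], u2, pi, C)
        assert tp_marginal_mean(pi, mu, C) == pytest.approx(np.exp(xb + u2), rel=1e-12)

    def test_mtp_marginal_mean_monte_carlo(self):
        # overall mean of Y (zeros included) equals exp(x'beta + u2)
        rng = np.random.default_rng(31)
        xb, u2, pi = 0.4, 0.0, 0.7
        k = sigma = 0.7
        C = offset_C(sigma, k)
        mu = float(mtp_location([1.0], [xb], u2, pi, C))
        n = 200_000
        nz = rng.random(n) < pi
        y = np.zeros(n)
        y[nz] = gg_sample(GGParams(k, sigma, mu), int(nz.sum()), rng)
        se = y.std() / np.sqrt(n)
        assert abs(y.mean() - np.exp(0.4)) < 3 * se


class TestTpMarginalMean:
    @pytest.mark.parametrize("pi,mu,C,expect", [
        (0.0, 3.0, 1.0, 0.0),
        (1.0, 0.0, 0.0, 1.0),
        (0.6, 0.2, 0.1, 0.6 * np.exp(0.3)),
    ])
    def test_values(self, pi, mu, C, expect):
        assert tp_marginal_mean(pi, mu, C) == pytest.approx(expect, rel=1e-12)


class TestSubjectIntegrand:
    def test_single_zero_record(self):
        pv = ParameterVector(np.array([0.0]), 1.0, 1.0, RandomEffectsCov(1, 1, 0),
                             alpha=np.array([0.0]))
        val = subject_integrand([0.0], [[1.0]], [[1.0]], pv, SPEC_MTP, (0.0, 0.0))
        assert val == pytest.approx(0.5, rel=1e-12)

    def test_single_positive_record_tp_gamma(self):
        # expit(0) * Exponential(1) density at y=1 = 0.5 * e^-1
        pv = ParameterVector(np.array([0.0]), 1.0, 1.0, RandomEffectsCov(1, 1, 0),
                             alpha=np.array([0.0]))
        val = subject_integrand([1.0], [[1.0]], [[1.0]], pv, SPEC_TP, (0.0, 0.0))
        assert val == pytest.approx(0.5 * np.exp(-1.0), rel=1e-12)

    def test_degenerate_random_effects_constant(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        pv = ParameterVector(toy_params.cont_coef, toy_params.k, toy_params.sigma,
                             RandomEffectsCov(0, 0, 0), alpha=toy_params.alpha)
        sl = ds.subject_slice(0)
        base = subject_log_integrand(ds.y[sl], ds.Z[sl], ds.X[sl], pv, SPEC_MTP, (0.0, 0.0))
        # with zero variances, the marginal likelihood equals the integrand at 0
        from mtplong.inference import marginal_subject_loglik

        marg = marginal_subject_loglik(ds.y[sl], ds.Z[sl], ds.X[sl], pv, SPEC_MTP)
        assert marg == pytest.approx(base, rel=1e-12)

    def test_factorizes_over_subjects(self, toy_params, five_subject_panel):
        ds = five_subject_panel
        u = (0.3, -0.2)
        total = subject_log_integrand(ds.y, ds.Z, ds.X, toy_params, SPEC_MTP, u)
        # NB: a single subject holding all records gives the same log integrand
        per = sum(
            subject_log_integrand(ds.y[ds.subject_slice(i)], ds.Z[ds.subject_slice(i)],
                                  ds.X[ds.subject_slice(i)], toy_params, SPEC_MTP, u)
            for i in range(ds.n_subjects)
        )
        assert total == pytest.approx(per, rel=1e-12)


class TestModelSpecValidation:
    def test_unknown_family(self):
        with pytest.raises(ValueError):
            ModelSpec("three_part", "gamma")

    def test_unknown_distribution(self):
        with pytest.raises(ValueError):
            ModelSpec("mtp", "beta")

    def test_re_cov_psd(self):
        with pytest.raises(ValueError):
            RandomEffectsCov(1.0, 1.0, 1.5)

    def test_uncorrelated_forces_zero_cov(self):
        re = RandomEffectsCov(1.0, 1.0, 0.5, correlated=False)
        assert re.cov12 == 0.0

    def test_n_free_params_table_layout(self):
        # 4 binary + 8 continuous covariates, gamma: 4 + 8 + 1 + 3 = 16
        pv = ParameterVector(np.zeros(8), 0.5, 0.5, RandomEffectsCov(1, 1, 0.2),
                             alpha=np.zeros(4))
        assert pv.n_free_params(ModelSpec("mtp", "gamma")) == 16
        assert pv.n_free_params(ModelSpec("mtp", "gg")) == 17
        assert pv.n_free_params(ModelSpec("tp_uncorrelated", "gamma")) == 15
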
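"""Likelihood core: linear predictors, hurdle density, covariance, posterior."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

from hurdlema.model import (
    HurdleGammaPosterior,
    ModelSpec,
    ParameterSet,
    corr_chol_from_cpc,
    cpc_from_corr,
    hurdle_loglik,
    linear_predictor_gamma,
    linear_predictor_zero,
    log_posterior,
    random_effects_cov,
)
from hurdlema.simulate import SimulationDesign, paper_scale_truth, simulate_dataset


def _intercept_params(**kw):
    base = dict(beta_zero=[-0.06], beta_gamma=[6.1], re_sd=[0.23, 0.14],
                re_corr=[[1, 0.77], [0.77, 1]], shape=2.0)
    base.update(kw)
    return ParameterSet(**base)


class TestModelSpec:
    def test_random_slope_must_be_fixed(self):
        with pytest.raises(ValueError, match="EA"):
            ModelSpec(zero_random=["EA"])

    def test_dimensions_and_names(self):
        spec = ModelSpec(zero_fixed=["EA"], gamma_fixed=["gender", "EA"],
                         zero_random=["EA"], gamma_random=["EA"])
        assert spec.n_random == 4
        names = spec.parameter_names()
        # 3 + 2 fixed? zero: intercept + EA; gamma: intercept + gender + EA
        assert names[:5] == ["b_zero_Intercept", "b_zero_EA",
                             "b_gamma_Intercept", "b_gamma_gender", "b_gamma_EA"]
        assert sum(n.startswith("cor_") for n in names) == 6
        assert names[-1] == "shape"

    def test_cross_part_flag_drops_cross_pairs(self):
        spec = ModelSpec(cross_part_correlated=False)
        assert spec.correlation_pairs() == []
        spec4 = ModelSpec(zero_fixed=["EA"], zero_random=["EA"],
                          gamma_fixed=["EA"], gamma_random=["EA"],
                          cross_part_correlated=False)
        assert spec4.correlation_pairs() == [(0, 1), (2, 3)]

    def test_yaml_roundtrip(self, tmp_path):
        spec = ModelSpec(gamma_fixed=["gender"], cross_part_correlated=False)
        spec.to_yaml(tmp_path / "m.yaml")
        assert ModelSpec.from_yaml(tmp_path / "m.yaml") == spec


class TestLinearPredictors:
    spec = ModelSpec(zero_fixed=["EA"], gamma_fixed=["gender"])
    params = ParameterSet(beta_zero=[-0.06, -0.04], beta_gamma=[6.27, -0.25],
                          re_sd=[0.23, 0.14], re_corr=[[1, 0.77], [0.77, 1]],
                          shape=2.0)

    def test_intercept_only_row(self):
        row = {"EA": 0.0, "gender": 0.0}
        assert linear_predictor_zero(row, self.params, [0, 0], self.spec) == -0.06
        assert linear_predictor_gamma(row, self.params, [0, 0], self.spec) == 6.27

    def test_covariate_contribution(self):
        row = {"EA": 1.0, "gender": 1.0}
        eta0 = linear_predictor_zero(row, self.params, [0, 0], self.spec)
        eta1 = linear_predictor_gamma(row, self.params, [0, 0], self.spec)
        assert eta0 == pytest.approx(-0.10)
        assert eta1 == pytest.approx(6.02)

    def test_random_effects_enter(self):
        row = {"EA": 0.0, "gender": 0.0}
        eta0 = linear_predictor_zero(row, self.params, [0.5, -0.2], self.spec)
        eta1 = linear_predictor_gamma(row, self.params, [0.5, -0.2], self.spec)
        assert eta0 == pytest.approx(-0.06 + 0.5)
        assert eta1 == pytest.approx(6.27 - 0.2)


class TestHurdleLoglik:
    def test_zero_at_symmetric_logit(self):
        assert hurdle_loglik(0.0, 0.0, 5.0, 1.0) == pytest.approx(np.log(0.5))

    def test_shape_one_is_exponential(self):
        # alpha=1 collapses the gamma to Exp(mean mu): independent closed form
        y, eta0, eta1 = 445.9, -0.06, 6.1
        mu = np.exp(eta1)
        expected = np.log(1 - expit(eta0)) + (-np.log(mu) - y / mu)
        assert hurdle_loglik(y, eta0, eta1, 1.0) == pytest.approx(expected)

    def test_matches_scipy_gamma_density(self):
        # shape-mean parameterization: rate alpha/mu <=> scale mu/alpha
        y, eta0, eta1, a = 123.4, 0.3, 5.0, 2.7
        mu = np.exp(eta1)
        expected = (np.log(1 - expit(eta0))
                    + stats.gamma.logpdf(y, a=a, scale=mu / a))
        assert hurdle_loglik(y, eta0, eta1, a) == pytest.approx(expected)

    @pytest.mark.parametrize("eta0", [-1.0, 0.0, 1.5])
    @pytest.mark.parametrize("eta1", [0.0, 2.0, 6.1])
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 8.0])
    def test_total_mass_is_one(self, eta0, eta1, alpha):
        # atom at zero plus gamma mass integrates to 1 (numerical quadrature)
        atom = expit(eta0)
        dens = lambda y: np.exp(hurdle_loglik(y, eta0, eta1, alpha))
        mu = np.exp(eta1)
        mass = (integrate.quad(dens, 0, mu, limit=200)[0]
                + integrate.quad(dens, mu, np.inf, limit=200)[0])
        assert atom + mass == pytest.approx(1.0, abs=1e-6)

    def test_monotonicity_in_eta(self):
        etas = np.linspace(-2, 2, 9)
        pis = expit(etas)
        assert np.all(np.diff(pis) > 0)
        ll = hurdle_loglik(np.zeros(9), etas, 1.0, 1.0)
        assert np.all(np.diff(ll) > 0)  # log pi increases with eta0

    def test_cv_shrinks_as_shape_grows(self):
        # coefficient of variation of the positive part is 1/sqrt(alpha)
        rng = np.random.default_rng(0)
        mu = 445.9
        for alpha in (1.0, 10.0, 100.0):
            y = rng.gamma(alpha, mu / alpha, 20000)
            assert y.std() / y.mean() == pytest.approx(alpha ** -0.5, rel=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hurdle_loglik(-1.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            hurdle_loglik(1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            hurdle_loglik(1.0, np.inf, 0.0, 1.0)


class TestCovariance:
    def test_hand_arithmetic(self):
        S = random_effects_cov([0.23, 0.14], [[1, 0.77], [0.77, 1]])
        assert S[0, 1] == pytest.approx(0.23 * 0.14 * 0.77)
        assert S[0, 0] == pytest.approx(0.23 ** 2)

    def test_zero_corr_is_diagonal(self):
        S = random_effects_cov([1.0, 2.0], np.eye(2))
        np.testing.assert_allclose(S, np.diag([1.0, 4.0]))

    def test_roundtrip(self):
        sd = np.array([0.5, 1.5, 2.0])
        R = np.array([[1, 0.3, -0.2], [0.3, 1, 0.5], [-0.2, 0.5, 1]])
        S = random_effects_cov(sd, R)
        sd_back = np.sqrt(np.diag(S))
        np.testing.assert_allclose(sd_back, sd)
        np.testing.assert_allclose(S / np.outer(sd_back, sd_back), R)

    def test_invalid_corr_rejected(self):
        bad = np.array([[1, 2], [2, 1]])  # not PSD
        with pytest.raises(ValueError):
            random_effects_cov([1, 1], bad)

    def test_cpc_transform_roundtrip(self):
        R = np.array([[1, 0.3, -0.2], [0.3, 1, 0.5], [-0.2, 0.5, 1]])
        z = cpc_from_corr(R)
        L = corr_chol_from_cpc(z, 3)
        np.testing.assert_allclose(L @ L.T, R, atol=1e-12)


class TestLogPosterior:
    def test_empty_dataset_is_prior_only(self, tiny_dataset):
        import pandas as pd

        from hurdlema.data import EmaDataset
        data, _ = tiny_dataset
        empty = EmaDataset(data.table.iloc[:0].copy())
        spec = ModelSpec()
        params = _intercept_params()
        u = np.zeros((0, 2))
        lp = log_posterior(params, u, empty, spec)
        assert np.isfinite(lp)
        # likelihood-free: changing shape only moves the prior term
        lp2 = log_posterior(_intercept_params(shape=3.0), u, empty, spec)
        assert lp != lp2

    def test_single_zero_row_closed_form(self):
        import pandas as pd

        from hurdlema.data import EmaDataset
        t = pd.DataFrame({"participant_id": [1], "prompt_index": [1],
                          "day": [1], "clock_time": [8.0], "outcome": [0.0]})
        data = EmaDataset(t)
        spec = ModelSpec()
        params = _intercept_params()
        u = np.zeros((1, 2))
        lp = log_posterior(params, u, data, spec)
        lp_no_data = log_posterior(params, np.zeros((0, 2)),
                                   EmaDataset(t.iloc[:0].copy()), spec)
        S = random_effects_cov(params.re_sd, params.re_corr)
        mvn0 = stats.multivariate_normal(np.zeros(2), S).logpdf([0, 0])
        assert lp - lp_no_data == pytest.approx(np.log(expit(-0.06)) + mvn0)

    def test_cross_part_correlation_changes_value_iff_nonzero_u(self, tiny_dataset):
        data, truth = tiny_dataset
        spec = ModelSpec()
        spec_nc = ModelSpec(cross_part_correlated=False)
        params = _intercept_params()
        u = truth["random_effects"]
        lp_corr = log_posterior(params, u, data, spec)
        lp_block = log_posterior(params, u, data, spec_nc)
        assert lp_corr != lp_block
        params0 = _intercept_params(re_corr=np.eye(2))
        assert log_posterior(params0, u, data, spec) == pytest.approx(
            log_posterior(params0, u, data, spec_nc))

    def test_dimension_mismatch_rejected(self, tiny_dataset):
        data, _ = tiny_dataset
        with pytest.raises(ValueError):
            log_posterior(_intercept_params(), np.zeros((3, 2)), data, ModelSpec())


class TestGradient:
    @pytest.mark.parametrize("spec,params", [
        (ModelSpec(), paper_scale_truth()),
        (ModelSpec(zero_fixed=["EA"], gamma_fixed=["gender", "EA"],
                   zero_random=["EA"], gamma_random=["EA"]),
         ParameterSet(beta_zero=[-0.06, -0.04], beta_gamma=[6.27, -0.25, 0.02],
                      re_sd=[0.23, 0.11, 0.14, 0.05],
                      re_corr=np.array([[1, .3, .5, -.2], [.3, 1, .1, .2],
                                        [.5, .1, 1, .4], [-.2, .2, .4, 1]]),
                      shape=2.0)),
    ])
    def test_matches_finite_differences(self, spec, params):
        design = SimulationDesign(n_participants=6, prompts_per_day=3,
                                  n_days=2, params=params, spec=spec, seed=9)
        data, _ = simulate_dataset(design)
        post = HurdleGammaPosterior(data, spec)
        rng = np.random.default_rng(1)
        theta = post.initial_point(rng, jitter=0.3)
        _, g = post.logp_grad(theta)
        eps = 1e-6
        for i in rng.choice(post.n_free, size=min(25, post.n_free), replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp(tp) - post.logp(tm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_constrain_orders_parameters(self):
        design = SimulationDesign(n_participants=4, prompts_per_day=3,
                                  n_days=1, seed=2)
        data, _ = simulate_dataset(design)
        post = HurdleGammaPosterior(data, ModelSpec())
        theta = post.initial_point(np.random.default_rng(0), jitter=0.0)
        out = post.constrain(theta)
        assert out.shape == (len(post.parameter_names),)
        # sds positive, correlation in [-1, 1], shape positive
        assert out[2] > 0 and out[3] > 0 and -1 <= out[4] <= 1 and out[5] > 0
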
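import numpy as np
import pytest
from scipy import stats

import hsekit as hk
from hsekit.errors import DomainError

from conftest import panel_from_eps
from oracles import bc92_loglik_quadrature, bc92_te_quadrature

ZERO_BETA = np.zeros(3)


def loglik_on_eps(eps, sigma_sq, gamma, mu, eta):
    params = {"beta": ZERO_BETA, "sigma_sq": sigma_sq, "gamma": gamma,
              "mu": mu, "eta": eta}
    return hk.loglik_timevarying(params, panel_from_eps(eps))


class TestLoglik:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, T = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        eps = rng.normal(0, 1, (n, T))
        sigma_sq = float(rng.uniform(0.2, 3.0))
        gamma = float(rng.uniform(0.05, 0.95))
        mu = float(rng.uniform(-1.0, 3.0))
        eta = float(rng.uniform(-0.3, 0.3))
        analytic = loglik_on_eps(eps, sigma_sq, gamma, mu, eta)
        oracle = bc92_loglik_quadrature(eps, sigma_sq, gamma, mu, eta)
        assert analytic == pytest.approx(oracle, abs=1e-6)

    def test_gamma_to_zero_approaches_ols_likelihood(self):
        eps = np.array([[0.5, -0.3], [0.2, -0.1]])
        ols = float(np.sum(stats.norm.logpdf(eps, scale=1.0)))
        near = loglik_on_eps(eps, 1.0, 1e-8, 0.0, 0.1)
        assert abs(near - ols) <= 1e-4

    def test_half_normal_is_truncated_normal_with_mu_zero(self):
        eps = np.array([[0.4, -0.2, 0.1]])
        params = {"beta": ZERO_BETA, "sigma_sq": 1.3, "gamma": 0.6,
                  "mu": 0.0, "eta": 0.05}
        panel = panel_from_eps(eps)
        tn = hk.loglik_timevarying(params, panel,
                                   hk.FrontierSpec(inefficiency="truncated_normal"))
        # mu in params must be ignored under the half-normal spec
        hn = hk.loglik_timevarying({**params, "mu": 99.0}, panel,
                                   hk.FrontierSpec(inefficiency="half_normal"))
        assert tn == pytest.approx(hn, abs=1e-12)

    def test_domain_errors(self):
        eps = np.zeros((1, 2))
        with pytest.raises(DomainError):
            loglik_on_eps(eps, -1.0, 0.5, 0.0, 0.0)
        with pytest.raises(DomainError):
            loglik_on_eps(eps, 1.0, 1.5, 0.0, 0.0)


class TestDecayAndGamma:
    def test_decay_examples(self):
        assert hk.decay_factor(11, 11, 0.5) == 1.0
        assert hk.decay_factor(1, 11, 0.014) == pytest.approx(np.exp(0.14), abs=1e-12)
        series = hk.decay_factor(np.arange(1, 12), 11, 0.02)
        assert (np.diff(series) < 0).all()

    def test_gamma_share(self):
        assert hk.gamma_share(0.0, 1.0) == 0.0
        assert hk.gamma_share(1.0, 0.0) == 1.0
        assert hk.gamma_share(1.47857, 0.00743) == pytest.approx(0.995, abs=5e-4)
        with pytest.raises(DomainError):
            hk.gamma_share(0.0, 0.0)


class TestLikelihoodRatio:
    def test_published_model_comparison_value(self):
        res = hk.likelihood_ratio_test(232.519, 115.321, 3)
        assert res["lr"] == pytest.approx(-234.396, abs=1e-9)
        assert not res["reject_h0"]

    def test_equal_likelihoods_give_zero(self):
        assert hk.likelihood_ratio_test(-10.0, -10.0, 2)["lr"] == 0.0

    def test_critical_values(self):
        res = hk.likelihood_ratio_test(0.0, 10.0, 3)
        assert res["chi2_critical"] == pytest.approx(7.8147, abs=1e-4)
        assert res["kodde_palm_critical"] == pytest.approx(7.045, abs=1e-3)
        assert res["reject_h0"]  # LR = 20 exceeds both


class TestPredictTE:
    def _fit_for(self, eps, sigma_sq, gamma, mu, eta):
        return hk.FrontierFit(spec=hk.FrontierSpec(), beta=ZERO_BETA,
                              sigma_sq=sigma_sq, gamma=gamma, mu=mu, eta=eta,
                              loglik=0.0, converged=True,
                              n_units=eps.shape[0], n_periods=eps.shape[1])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        eps = rng.normal(0, 1, (2, 3))
        sigma_sq, gamma = 1.4, float(rng.uniform(0.2, 0.9))
        mu, eta = float(rng.uniform(0, 2)), float(rng.uniform(-0.2, 0.2))
        fit = self._fit_for(eps, sigma_sq, gamma, mu, eta)
        te = hk.predict_te(fit, panel_from_eps(eps)).wide().to_numpy()
        for i in range(2):
            oracle = bc92_te_quadrature(eps[i], sigma_sq, gamma, mu, eta)
            assert np.allclose(te[i], oracle, atol=1e-6)

    def test_vanishing_inefficiency_gives_te_near_one(self):
        eps = np.random.default_rng(1).normal(0, 1, (3, 4))
        fit = self._fit_for(eps, 1.0, 1e-9, 0.0, 0.0)
        te = hk.predict_te(fit, panel_from_eps(eps)).data["te"]
        assert (te >= 0.999).all()

    def test_series_increase_over_time_for_positive_eta(self):
        eps = np.random.default_rng(2).normal(0, 0.5, (4, 5))
        fit = self._fit_for(eps, 1.5, 0.9, 1.0, 0.1)
        wide = hk.predict_te(fit, panel_from_eps(eps)).wide().to_numpy()
        assert (np.diff(wide, axis=1) > 0).all()
        assert ((wide > 0) & (wide < 1)).all()


class TestFit:
    def test_recovers_no_inefficiency_case(self):
        truth = hk.FrontierTruth(gamma=0.0, sigma_sq=0.05, n_units=20,
                                 n_periods=5, seed=8)
        panel, _, _ = hk.generate_panel(truth)
        fit = hk.fit_frontier(panel, predict=True)
        assert fit.gamma < 0.2
        X = hk.frontier.design_matrix(panel, fit.spec)
        y = panel.data["ln_output_index"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta[1:], beta_ols[1:], atol=0.05)
        assert (fit.te_panel.data["te"] > 0.9).all()

    def test_translog_nests_cobb_douglas(self):
        truth = hk.FrontierTruth(n_units=12, n_periods=4, seed=21)
        panel, _, _ = hk.generate_panel(truth)
        cd = hk.fit_frontier(panel, hk.FrontierSpec(form="cobb_douglas"),
                             predict=False)
        tl = hk.fit_frontier(panel, hk.FrontierSpec(form="translog"),
                             predict=False)
        assert tl.loglik >= cd.loglik - 1e-4

    def test_eta_zero_data_yields_small_eta_estimate(self):
        errs = []
        for seed in (31, 32, 33):
            truth = hk.FrontierTruth(eta=0.0, n_units=20, n_periods=6, seed=seed)
            panel, _, _ = hk.generate_panel(truth)
            fit = hk.fit_frontier(panel, predict=False)
            errs.append(abs(fit.eta))
        assert np.median(errs) < 0.02
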
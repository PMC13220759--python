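"""Truncated negative-binomial distribution, regression MLE, residual tests,
MLFC and BH-FDR."""

import numpy as np
import pytest
from scipy import special, stats

from epiburden import tnb


def sample_tnb(rng, mu, theta, t, size=None):
    """Sample from the truncated NB by rejection (test-side oracle sampler)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (size,) if size else np.shape(mu))
    p = theta / (theta + mu)
    out = np.full(mu.shape, -1, dtype=int)
    while (out <= t).any():
        todo = out <= t
        out[todo] = stats.nbinom.rvs(theta, p[todo], random_state=rng)
    return out


class TestPmf:
    @pytest.mark.parametrize(
        "mu,theta,t",
        [(1.5, 2.0, 0), (3.0, 0.7, 1), (0.8, 5.0, 2), (10.0, 1.2, -1)],
    )
    def test_normalizes_over_support(self, mu, theta, t):
        ys = np.arange(max(t + 1, 0), 4000)
        total = tnb.tnb_pmf(ys, mu, theta, t).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_untruncated_limit_matches_scipy(self):
        mu, theta = 2.5, 1.3
        p = theta / (theta + mu)
        ys = np.arange(0, 50)
        np.testing.assert_allclose(
            tnb.tnb_pmf(ys, mu, theta, -1), stats.nbinom.pmf(ys, theta, p), rtol=1e-12
        )

    def test_value_against_hand_formula(self):
        """(y=2, mu=1.5, theta=2, t=0): NB pmf from the Gamma-function formula
        divided by 1 - pmf(0)."""
        mu, theta = 1.5, 2.0
        p = theta / (theta + mu)
        q = mu / (theta + mu)

        def nb_hand(y):
            return (
                np.exp(
                    special.gammaln(y + theta)
                    - special.gammaln(theta)
                    - special.gammaln(y + 1)
                )
                * p**theta
                * q**y
            )

        expected = nb_hand(2) / (1.0 - nb_hand(0))
        assert tnb.tnb_pmf(2, mu, theta, 0) == pytest.approx(expected, rel=1e-12)

    def test_zero_below_truncation(self):
        assert tnb.tnb_pmf(1, 2.0, 1.0, 1) == 0.0
        assert tnb.tnb_pmf(0, 2.0, 1.0, 0) == 0.0

    def test_poisson_limit(self):
        """theta -> infinity recovers a truncated Poisson."""
        mu, t = 3.0, 1
        ys = np.arange(t + 1, 30)
        pois = stats.poisson.pmf(ys, mu) / (1.0 - stats.poisson.cdf(t, mu))
        np.testing.assert_allclose(tnb.tnb_pmf(ys, mu, 1e6, t), pois, atol=1e-4)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            tnb.tnb_pmf(1, -1.0, 1.0, 0)
        with pytest.raises(ValueError):
            tnb.tnb_pmf(1, np.inf, 1.0, 0)


class TestFit:
    def test_parameter_recovery(self, rng):
        """Self-simulated TNB data: coefficients recovered within 3 SE,
        dispersion within 15% relative error."""
        n = 20000
        X = np.column_stack([rng.normal(0, 1, n), rng.uniform(0, 2, n)])
        beta = np.array([2.0, 0.4, -0.3])
        theta, t = 1.2, 1
        mu = np.exp(beta[0] + X @ beta[1:])
        y = sample_tnb(rng, mu, theta, t, size=n)
        model = tnb.fit_tnb(y, X, t=t, compute_se=True)
        assert model.converged
        assert np.all(np.abs(model.beta - beta) < 3 * model.beta_se)
        assert abs(model.theta - theta) / theta < 0.15

    def test_intercept_only_matches_truncated_mean(self, rng):
        """With constant predictors the MLE equates the fitted truncated mean
        with the sample mean."""
        y = sample_tnb(rng, np.full(8000, 4.0), 1.5, t=1, size=None)
        X = np.zeros((len(y), 1))
        model = tnb.fit_tnb(y, X, t=1, min_pairs=100)
        mu = tnb.predict_mu(model, X)
        assert np.ptp(mu) < 1e-8
        fitted_tmean = tnb.truncated_mean(mu[0], model.theta, 1)
        assert fitted_tmean == pytest.approx(y.mean(), rel=1e-4)

    def test_null_predictor_changes_nothing(self, rng):
        n = 6000
        X = rng.normal(0, 1, (n, 2))
        mu = np.exp(1.5 + 0.3 * X[:, 0])
        y = sample_tnb(rng, mu, 1.0, t=0, size=None)
        m1 = tnb.fit_tnb(y, X, t=0, min_pairs=100)
        m2 = tnb.fit_tnb(y, np.column_stack([X, np.full(n, 7.0)]), t=0, min_pairs=100)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-3)
        np.testing.assert_allclose(
            tnb.predict_mu(m1, X),
            tnb.predict_mu(m2, np.column_stack([X, np.full(n, 7.0)])),
            rtol=1e-3,
        )

    def test_stop_rule(self, rng):
        y = sample_tnb(rng, np.full(100, 3.0), 1.0, t=0, size=None)
        with pytest.raises(tnb.BackgroundTooSmall):
            tnb.fit_tnb(y, np.zeros((100, 1)), t=0)  # default minimum is 5000

    def test_optimization_improves_on_start(self, rng):
        """The accepted optimum never has lower likelihood than the start."""
        n = 6000
        X = rng.normal(0, 1, (n, 1))
        y = sample_tnb(rng, np.exp(1.0 + 0.5 * X[:, 0]), 0.8, t=0, size=None)
        from epiburden.tnb import _negll_and_grad

        Z = (X - X.mean(0)) / X.std(0)
        g1 = special.gammaln(y + 1.0)
        start = np.array([np.log(y.mean()), 0.0, 0.0])
        nll_start, _ = _negll_and_grad(start, Z, y.astype(float), 0, g1)
        model = tnb.fit_tnb(y, X, t=0, min_pairs=100)
        assert model.loglik >= -nll_start * n - 1e-6


class TestPredict:
    def test_zero_coefficients_give_unit_mean(self):
        model = tnb.TNBModel(
            beta=np.zeros(3), theta=1.0, t=0, b=None, loglik=0.0,
            converged=True, n_pairs_fit=0,
        )
        assert tnb.predict_mu(model, np.array([[5.0, -2.0]]))[0] == pytest.approx(1.0)

    def test_intercept_log5(self):
        model = tnb.TNBModel(
            beta=np.array([np.log(5.0), 0.0]), theta=1.0, t=0, b=None,
            loglik=0.0, converged=True, n_pairs_fit=0,
        )
        assert tnb.predict_mu(model, np.array([[3.0]]))[0] == pytest.approx(5.0)

    def test_matches_dot_product(self, rng):
        beta = np.array([0.5, 0.2, -0.1, 0.05])
        model = tnb.TNBModel(
            beta=beta, theta=1.0, t=0, b=None, loglik=0.0,
            converged=True, n_pairs_fit=0,
        )
        X = rng.normal(0, 1, (20, 3))
        np.testing.assert_allclose(
            tnb.predict_mu(model, X), np.exp(beta[0] + X @ beta[1:]), rtol=1e-12
        )

    def test_prediction_clipped_to_fit_range(self):
        model = tnb.TNBModel(
            beta=np.array([0.0, 1.0]), theta=1.0, t=0, b=None, loglik=0.0,
            converged=True, n_pairs_fit=0, eta_range=(-1.0, 2.0),
        )
        mu = tnb.predict_mu(model, np.array([[10.0], [-10.0]]))
        assert mu[0] == pytest.approx(np.exp(2.0))
        assert mu[1] == pytest.approx(np.exp(-1.0))


class TestResiduals:
    def test_background_standardization_is_exact(self, rng):
        y = sample_tnb(rng, np.full(5000, 6.0), 1.0, t=0, size=None)
        mu = np.full(len(y), 6.0)
        d = tnb.deviance_residuals(y, mu, 1.0, 0)
        d_std, scale = tnb.standardize_residuals(d, np.ones(len(y), dtype=bool))
        assert d_std.mean() == pytest.approx(0.0, abs=1e-8)
        assert d_std.var() == pytest.approx(1.0, abs=1e-8)
        # stored scale reproduces the same transform
        np.testing.assert_allclose(tnb.apply_residual_scale(d, scale), d_std)

    def test_pvalues_from_normal_tail(self):
        assert tnb.pvalues_from_dstd(np.array([0.0]))[0] == pytest.approx(0.5)
        assert tnb.pvalues_from_dstd(np.array([1.6449]))[0] == pytest.approx(
            0.05, abs=1e-4
        )

    def test_below_truncation_gets_p_one(self):
        d = tnb.deviance_residuals(np.array([0, 1, 5]), np.full(3, 4.0), 1.0, 1)
        assert np.isnan(d[0]) and np.isnan(d[1]) and np.isfinite(d[2])
        p = tnb.pvalues_from_dstd(d)
        assert p[0] == 1.0 and p[1] == 1.0

    def test_null_pvalues_approximately_uniform(self, rng):
        """Self-simulated null: standardized deviance residual p-values are
        near-uniform (KS statistic below 0.02 at n = 20000)."""
        n = 20000
        X = rng.normal(0, 1, (n, 1))
        # moderate means: at very low counts the discreteness of Y alone
        # puts a floor on the KS distance regardless of calibration
        mu = np.exp(4.0 + 0.5 * X[:, 0])
        theta, t = 2.0, 1
        y = sample_tnb(rng, mu, theta, t, size=None)
        model = tnb.fit_tnb(y, X, t=t)
        mu_hat = tnb.predict_mu(model, X)
        d = tnb.deviance_residuals(y, mu_hat, model.theta, t)
        d_std, _ = tnb.standardize_residuals(d, np.ones(n, dtype=bool))
        p = tnb.pvalues_from_dstd(d_std)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.02


class TestMlfc:
    def test_exact_uniform_quantiles_give_zero(self):
        n = 500
        p = np.arange(1, n + 1) / (n + 1)
        assert tnb.mlfc(p) == pytest.approx(0.0, abs=1e-12)

    def test_halved_uniform_gives_one(self):
        n = 500
        p = np.arange(1, n + 1) / (n + 1) / 2.0
        assert tnb.mlfc(p) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        p = rng.uniform(0, 1, 1000)
        ps = np.sort(p)
        expected = np.mean(
            np.abs(np.log2(ps / (np.arange(1, 1001) / 1001.0)))
        )
        assert tnb.mlfc(p) == pytest.approx(expected, rel=1e-12)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            tnb.mlfc([0.5])
        with pytest.raises(ValueError):
            tnb.mlfc([0.5, 1.5])


class TestBhFdr:
    def test_single_pvalue(self):
        assert tnb.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            tnb.bh_fdr([0.01, 0.02, 0.03, 1.0]), [0.04, 0.04, 0.04, 1.0]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(tnb.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 200)
        q = tnb.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
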
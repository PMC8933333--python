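"""Variational-Laplace engine: exactness, hyperpriors, and Occam behavior."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import multivariate_normal

from bdcm.inversion import (
    GammaHyper,
    InversionSettings,
    invert,
    predict,
    set_hyperpriors,
)


class LinearModel:
    """y = X theta + noise; the conjugate case with a closed-form evidence."""

    def __init__(self, X, prior_mean, prior_var):
        self.X = X
        self.prior_mean = np.asarray(prior_mean, dtype=float)
        self.prior_var = np.asarray(prior_var, dtype=float)
        self.param_names = [f"t{i}" for i in range(X.shape[1])]

    def predict(self, theta):
        return {"y": self.X @ theta}

    def log_evidence(self, y, lam):
        S0 = np.diag(self.prior_var)
        cov = self.X @ S0 @ self.X.T + np.eye(len(y)) / lam
        return multivariate_normal(mean=self.X @ self.prior_mean, cov=cov).logpdf(y)


@pytest.fixture()
def linear_problem(rng):
    n, d = 40, 3
    X = rng.normal(size=(n, d))
    prior_mean = np.array([0.5, -0.2, 0.0])
    prior_var = np.array([1.0, 0.5, 2.0])
    lam = 4.0
    theta = rng.normal(prior_mean, np.sqrt(prior_var))
    y = X @ theta + rng.normal(0, lam**-0.5, n)
    return LinearModel(X, prior_mean, prior_var), y, lam


class TestFreeEnergy:
    def test_matches_conjugate_log_evidence(self, linear_problem):
        model, y, lam = linear_problem
        res = invert(model, {"y": y}, {"y": GammaHyper(fixed=lam)})
        assert res.free_energy == pytest.approx(model.log_evidence(y, lam), abs=1e-3)
        assert res.converged

    def test_posterior_moments_match_conjugate_solution(self, linear_problem):
        model, y, lam = linear_problem
        res = invert(model, {"y": y}, {"y": GammaHyper(fixed=lam)})
        P0 = np.diag(1.0 / model.prior_var)
        P = lam * model.X.T @ model.X + P0
        m = np.linalg.solve(P, lam * model.X.T @ y + P0 @ model.prior_mean)
        np.testing.assert_allclose(res.posterior_mean, m, atol=1e-8)
        np.testing.assert_allclose(res.posterior_cov, np.linalg.inv(P), atol=1e-8)

    def test_all_fixed_model_gives_likelihood_at_prior_mean(self, linear_problem):
        model, y, lam = linear_problem
        fixed = LinearModel(model.X, model.prior_mean, np.zeros(3))
        res = invert(fixed, {"y": y}, {"y": GammaHyper(fixed=lam)})
        e = y - model.X @ model.prior_mean
        loglik = 0.5 * len(y) * (np.log(lam) - np.log(2 * np.pi)) - 0.5 * lam * e @ e
        assert res.free_energy == pytest.approx(loglik, abs=1e-10)
        assert res.iterations == 0
        np.testing.assert_array_equal(res.posterior_mean, model.prior_mean)

    def test_trace_nondecreasing_with_estimated_precision(self, linear_problem):
        model, y, _ = linear_problem
        hyper = set_hyperpriors((0.1, 0.9), float(np.var(y)))
        res = invert(model, {"y": y}, {"y": hyper})
        assert np.all(np.diff(res.f_trace) >= -1e-3)
        # the estimated precision lands near the generating value of 4
        assert 1.5 < res.precisions["y"]["mean"] < 10.0

    def test_occam_penalty_for_irrelevant_parameter(self, rng):
        """A free parameter whose true value is 0 cannot raise the evidence."""
        n = 60
        X = rng.normal(size=(n, 2))
        y = X[:, 0] * 0.8 + rng.normal(0, 0.3, n)
        lam = 1 / 0.3**2
        simple = LinearModel(X[:, :1], [0.0], [1.0])
        padded = LinearModel(X, [0.0, 0.0], [1.0, 1.0])
        f_simple = invert(simple, {"y": y}, {"y": GammaHyper(fixed=lam)}).free_energy
        f_padded = invert(padded, {"y": y}, {"y": GammaHyper(fixed=lam)}).free_energy
        assert f_padded <= f_simple + 1e-6

    def test_posterior_concentrates_with_data(self, rng):
        X = rng.normal(size=(30, 2))
        theta = np.array([0.5, -0.3])
        lam = 25.0
        y = X @ theta + rng.normal(0, lam**-0.5, 30)
        model1 = LinearModel(X, [0, 0], [1, 1])
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, X @ theta + rng.normal(0, lam**-0.5, 30)])
        model2 = LinearModel(X2, [0, 0], [1, 1])
        v1 = np.diag(invert(model1, {"y": y}, {"y": GammaHyper(fixed=lam)}).posterior_cov)
        v2 = np.diag(invert(model2, {"y": y2}, {"y": GammaHyper(fixed=lam)}).posterior_cov)
        assert np.all(v2 < v1)

    def test_multichannel_likelihood_is_additive(self, rng):
        """Two channels with one shared parameter beat either alone."""
        n = 25
        xa, xb = rng.normal(size=(2, n))
        theta = 0.7
        ya = xa * theta + rng.normal(0, 0.1, n)
        yb = xb * theta + rng.normal(0, 0.2, n)

        class TwoChannel:
            param_names = ["t"]
            prior_mean = np.array([0.0])
            prior_var = np.array([1.0])

            def predict(self, th):
                return {"a": xa * th[0], "b": xb * th[0]}

        hyper = {"a": GammaHyper(fixed=100.0), "b": GammaHyper(fixed=25.0)}
        res = invert(TwoChannel(), {"a": ya, "b": yb}, hyper)
        # precision-weighted combination of the two single-channel solutions
        p0 = 1.0
        pa, pb = 100 * xa @ xa, 25 * xb @ xb
        expected = (100 * xa @ ya + 25 * xb @ yb) / (p0 + pa + pb)
        assert res.posterior_mean[0] == pytest.approx(expected, abs=1e-6)


class TestHyperpriors:
    def test_quantiles_match_requested_interval(self):
        h = set_hyperpriors((0.1, 0.9), data_variance=1.0)
        q10 = gamma_dist.ppf(0.1, h.shape, scale=1 / h.rate)
        q90 = gamma_dist.ppf(0.9, h.shape, scale=1 / h.rate)
        assert 1 / q10 == pytest.approx(0.9, rel=1e-6)  # residual var at EV=0.1
        assert 1 / q90 == pytest.approx(0.1, rel=1e-6)  # residual var at EV=0.9

    def test_scale_equivariance(self):
        a = set_hyperpriors((0.2, 0.8), 1.0)
        b = set_hyperpriors((0.2, 0.8), 4.0)  # data scaled x2
        assert b.shape == pytest.approx(a.shape, rel=1e-9)
        assert b.rate == pytest.approx(4.0 * a.rate, rel=1e-9)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            set_hyperpriors((0.5, 0.5), 1.0)
        with pytest.raises(ValueError):
            set_hyperpriors((0.9, 0.1), 1.0)
        with pytest.raises(ValueError):
            set_hyperpriors((0.0, 0.9), 1.0)

    def test_invalid_gamma_hyper_rejected(self):
        with pytest.raises(ValueError):
            GammaHyper(shape=0.0, rate=1.0)


class TestPredict:
    def test_predictions_consistent_with_stored(self, linear_problem):
        model, y, lam = linear_problem
        res = invert(model, {"y": y}, {"y": GammaHyper(fixed=lam)})
        np.testing.assert_allclose(
            predict(res, model)["y"], res.predictions["y"], atol=1e-12
        )

    def test_fixed_parameter_prior_mean_steers_predictions(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ np.array([0.5, 1.0]) + rng.normal(0, 0.1, 20)
        # second parameter fixed: moving its prior mean must move the fit
        m1 = LinearModel(X, [0.0, 1.0], [1.0, 0.0])
        m2 = LinearModel(X, [0.0, 2.0], [1.0, 0.0])
        r1 = invert(m1, {"y": y}, {"y": GammaHyper(fixed=100.0)})
        r2 = invert(m2, {"y": y}, {"y": GammaHyper(fixed=100.0)})
        assert r1.posterior_mean[1] == 1.0
        assert r2.posterior_mean[1] == 2.0
        assert not np.allclose(r1.predictions["y"], r2.predictions["y"])

    def test_missing_hyperprior_rejected(self, linear_problem):
        model, y, _ = linear_problem
        with pytest.raises(ValueError, match="hyperprior"):
            invert(model, {"y": y}, {})

    def test_nonconvergence_flagged_not_raised(self, linear_problem):
        model, y, lam = linear_problem
        with pytest.warns(UserWarning, match="did not converge"):
            res = invert(
                model,
                {"y": y},
                {"y": GammaHyper(fixed=lam)},
                InversionSettings(max_iter=1, n_converged=2),
            )
        assert res.converged is False
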
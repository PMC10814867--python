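"""EM machinery: E-step posterior, weighted-logistic M-steps, outer loop."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import random_dataset, random_params
from ziber.data import Dataset, EstimationError, ZIBerParams
from ziber.em import (EMControls, e_step, fit_em, initialize, m_step_beta,
                      m_step_theta)
from ziber.likelihood import complete_loglik_beta, complete_loglik_theta


def _logit(q):
    return math.log(q / (1 - q))


def _controlled_dataset(p_vals, delta_vals, y):
    """Dataset whose per-observation p and delta equal the given values
    (identity designs with beta = theta = (0, 1))."""
    n = len(y)
    X = np.column_stack([np.ones(n), [_logit(v) for v in p_vals]])
    Z = np.column_stack([np.ones(n), [_logit(v) for v in delta_vals]])
    data = Dataset(y=np.asarray(y, float), X=X, Z=Z)
    params = ZIBerParams(beta=np.array([0.0, 1.0]), theta=np.array([0.0, 1.0]))
    return data, params


class TestEStep:
    def test_positive_outcomes_get_zero_weight(self):
        data, params = _controlled_dataset([0.3, 0.3], [0.6, 0.6], [1, 0])
        w = e_step(params, data)
        assert w[0] == 0.0 and w[1] > 0.0

    @pytest.mark.parametrize("delta, p, expected", [
        (0.5, 0.5, 2 / 3),
        (0.8, 0.3, 0.8 / 0.94),
    ])
    def test_closed_form_values(self, delta, p, expected):
        data, params = _controlled_dataset([p], [delta], [0])
        assert e_step(params, data)[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_bayes_enumeration(self, rng):
        """w equals the two-component posterior delta/(delta+(1-delta)(1-p))."""
        n = 500
        p = rng.uniform(0.01, 0.99, n)
        d = rng.uniform(0.01, 0.99, n)
        data, params = _controlled_dataset(p, d, np.zeros(n))
        w = e_step(params, data)
        oracle = d / (d + (1 - d) * (1 - p))
        np.testing.assert_allclose(w, oracle, rtol=0, atol=1e-12)


class TestMStepTheta:
    def test_intercept_only_closed_forms(self):
        Z = np.ones((8, 1))
        w = np.full(8, 0.5)
        assert m_step_theta(w, Z, np.zeros(1))[0] == pytest.approx(0.0, abs=1e-8)
        w = np.full(8, 0.25)
        assert m_step_theta(w, Z, np.zeros(1))[0] == pytest.approx(
            _logit(0.25), abs=1e-8)

    def test_matches_two_stage_grid_search(self, rng):
        """Dense (coarse-then-refined) grid maximiser of the fractional
        logistic objective agrees to 3 decimals."""
        n = 20
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0, 1, n)
        theta_hat = m_step_theta(w, Z, np.zeros(2))

        grid = np.arange(-4.0, 4.0, 0.05)
        t1, t2 = np.meshgrid(grid, grid, indexing="ij")
        cand = np.column_stack([t1.ravel(), t2.ravel()])
        vals = (cand @ Z.T * w).sum(axis=1) - np.logaddexp(0, cand @ Z.T).sum(axis=1)
        best = cand[int(np.argmax(vals))]
        fine1 = np.arange(best[0] - 0.06, best[0] + 0.06, 0.0005)
        fine2 = np.arange(best[1] - 0.06, best[1] + 0.06, 0.0005)
        f1, f2 = np.meshgrid(fine1, fine2, indexing="ij")
        cand = np.column_stack([f1.ravel(), f2.ravel()])
        vals = (cand @ Z.T * w).sum(axis=1) - np.logaddexp(0, cand @ Z.T).sum(axis=1)
        best = cand[int(np.argmax(vals))]
        np.testing.assert_allclose(theta_hat, best, rtol=0, atol=1e-3)

    def test_matches_statsmodels_glm(self, rng):
        n = 60
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.05, 0.95, n)
        ours = m_step_theta(w, Z, np.zeros(2))
        glm = sm.GLM(w, Z, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours, glm.params, rtol=0, atol=1e-6)

    def test_rejects_invalid_weights(self):
        with pytest.raises(ValueError):
            m_step_theta(np.array([1.5]), np.ones((1, 1)), np.zeros(1))


class TestMStepBeta:
    def test_zero_weights_reduce_to_ordinary_logistic(self, rng):
        data = random_dataset(rng, n=80)
        ours = m_step_beta(np.zeros(data.n), data, np.zeros(data.p))
        ref = sm.Logit(data.y, data.X).fit(disp=0)
        np.testing.assert_allclose(ours, ref.params, rtol=0, atol=1e-6)

    def test_intercept_only_weighted_closed_form(self):
        # all case weights 1, mean(y) = 0.2 -> logit(0.2)
        y = np.array([1.0, 0, 0, 0, 0] * 2)
        data = Dataset(y=y, X=np.ones((10, 1)), Z=np.ones((10, 1)))
        beta = m_step_beta(np.zeros(10), data, np.zeros(1))
        assert beta[0] == pytest.approx(_logit(0.2), abs=1e-8)

    def test_matches_grid_search_on_weighted_toy(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.4).astype(float)
        w = np.where(y == 1, 0.0, rng.uniform(0, 1, n))
        data = Dataset(y=y, X=X, Z=np.ones((n, 1)))
        beta_hat = m_step_beta(w, data, np.zeros(2))
        obj = lambda c: complete_loglik_beta(c, data, w)
        grid = np.arange(-4.0, 4.0, 0.05)
        b1, b2 = np.meshgrid(grid, grid, indexing="ij")
        cand = np.column_stack([b1.ravel(), b2.ravel()])
        vals = np.array([obj(c) for c in cand])
        best = cand[int(np.argmax(vals))]
        fine = [np.arange(b - 0.06, b + 0.06, 0.0005) for b in best]
        f1, f2 = np.meshgrid(*fine, indexing="ij")
        cand = np.column_stack([f1.ravel(), f2.ravel()])
        vals = np.array([obj(c) for c in cand])
        best = cand[int(np.argmax(vals))]
        np.testing.assert_allclose(beta_hat, best, rtol=0, atol=1e-3)

    def test_score_condition_at_optimum(self, rng):
        data = random_dataset(rng, n=100)
        w = np.where(data.y == 1, 0.0, rng.uniform(0, 0.9, data.n))
        beta = m_step_beta(w, data, np.zeros(data.p))
        from scipy.special import expit
        score = data.X.T @ ((1 - w) * (data.y - expit(data.X @ beta)))
        assert np.max(np.abs(score)) < 1e-6

    def test_rejects_nonzero_weight_on_positive(self, rng):
        data = random_dataset(rng, n=10)
        w = np.full(10, 0.3)
        if data.y.max() == 1:
            with pytest.raises(ValueError):
                m_step_beta(w, data, np.zeros(data.p))


class TestInitialize:
    def test_theta_starts_at_zero(self, rng):
        data = random_dataset(rng, n=50)
        init = initialize(data)
        np.testing.assert_array_equal(init.theta, np.zeros(data.k))

    def test_balanced_intercept_only_beta_is_zero(self):
        y = np.array([0.0, 1.0] * 6)
        data = Dataset(y=y, X=np.ones((12, 1)), Z=np.ones((12, 1)))
        assert initialize(data).beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_constant_outcome_raises(self):
        data = Dataset(y=np.zeros(8), X=np.ones((8, 1)), Z=np.ones((8, 1)))
        with pytest.raises(EstimationError):
            initialize(data)


class TestFitEM:
    def test_trace_is_monotone_on_random_data(self, rng):
        for _ in range(20):
            data = random_dataset(rng, n=60)
            fit = fit_em(data, EMControls(max_iter=30))
            assert np.all(np.diff(fit.loglik_trace) > -1e-8)

    def test_forced_single_iteration_does_not_converge(self, rng):
        data = random_dataset(rng, n=80)
        fit = fit_em(data, EMControls(max_iter=1))
        assert fit.n_iter == 1 and not fit.converged

    def test_fixed_point_of_converged_solution(self, rng):
        data = random_dataset(rng, n=120)
        controls = EMControls(max_iter=5000, accelerate=True)
        fit = fit_em(data, controls)
        assert fit.converged
        again = fit_em(data, EMControls(max_iter=1), init=fit.params)
        move = np.max(np.abs(again.params.concat() - fit.params.concat()))
        assert move < controls.param_tol

    def test_accelerated_matches_plain_fixed_point(self, rng):
        data = random_dataset(rng, n=150)
        plain = fit_em(data, EMControls(max_iter=2000))
        fast = fit_em(data, EMControls(max_iter=2000, accelerate=True))
        assert plain.converged and fast.converged
        assert np.all(np.diff(fast.loglik_trace) > -1e-8)
        np.testing.assert_allclose(fast.params.concat(), plain.params.concat(),
                                   rtol=0, atol=5e-3)

    def test_weights_zero_on_positives(self, rng):
        data = random_dataset(rng, n=70)
        fit = fit_em(data, EMControls(max_iter=10))
        assert np.all(fit.weights[data.y == 1.0] == 0.0)
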
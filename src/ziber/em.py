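"""EM estimation of the zero-inflated Bernoulli regression model.

The complete-data log-likelihood separates into two logistic terms, so each
EM iteration is:

* **E-step** — replace the latent structural-zero indicator by its posterior
  mean ``w_i``; for ``y_i = 1`` the observation cannot be a structural zero
  and ``w_i = 0``, otherwise ``w_i = delta_i / (1 - p_i (1 - delta_i))``.
* **M-step** — maximise the two terms separately: a logistic regression of
  the fractional response ``w`` on ``Z`` (updating theta) and a
  case-weighted logistic regression of ``y`` on ``X`` with weights
  ``1 - w`` (updating beta).

Both M-steps are concave and solved by Newton-Raphson/IRLS with
step-halving.  The outer loop stops when every coefficient moves by less
than ``param_tol`` between adjacent iterations, or after ``max_iter``
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data import Dataset, EstimationError, ZIBerParams
from .likelihood import event_probabilities, log1pexp, observed_loglik

__all__ = ["EMControls", "EMFit", "e_step", "m_step_theta", "m_step_beta",
           "initialize", "fit_em", "weighted_logistic_mle"]

# |linear predictor| beyond this at an M-step optimum, combined with a
# near-singular Hessian, is treated as separation (divergence to the
# boundary) rather than a usable maximum.
_SEPARATION_ETA = 30.0
_SEPARATION_RCOND = 1e-10


@dataclass(frozen=True)
class EMControls:
    """Tuning constants of the outer EM loop and the inner IRLS solver.

    ``accelerate`` switches on squared-extrapolation (SQUAREM-style)
    cycles: each cycle takes two plain EM steps, extrapolates along the
    observed step direction, and falls back to the plain two-step result
    whenever the extrapolated point does not improve the observed
    log-likelihood.  The fixed points are exactly those of plain EM and the
    log-likelihood trace stays monotone; convergence is typically reached
    in far fewer EM-map evaluations, which matters because the mixture is
    weakly identified and plain EM approaches the optimum very slowly.
    With ``accelerate``, ``max_iter`` counts EM-map evaluations.
    """

    max_iter: int = 50
    param_tol: float = 1e-5
    inner_tol: float = 1e-10
    inner_max_iter: int = 100
    accelerate: bool = False

    def __post_init__(self):
        if not (self.max_iter >= 1 and self.inner_max_iter >= 1
                and self.param_tol > 0 and self.inner_tol > 0):
            raise ValueError("EM controls must be positive")


@dataclass
class EMFit:
    """Raw output of the EM loop (wrapped by ``ZIBerResults``)."""

    params: ZIBerParams
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    weights: np.ndarray = field(repr=False, default=None)  # final E-step w


def e_step(params: ZIBerParams, data: Dataset) -> np.ndarray:
    """Posterior probability that each observation is a structural zero.

    Zero wherever ``y_i = 1``; the Bayes posterior
    delta / (delta + (1 - delta)(1 - p)) elsewhere.
    """
    probs = event_probabilities(params, data)
    denom = 1.0 - probs.p * (1.0 - probs.delta)
    with np.errstate(invalid="ignore"):
        w = np.where(denom > 0.0, probs.delta / denom, 0.0)
    w = np.where(data.y == 1.0, 0.0, w)
    return np.clip(w, 0.0, 1.0)


def weighted_logistic_mle(D: np.ndarray, resp: np.ndarray, case_w: np.ndarray,
                          start: np.ndarray, tol: float = 1e-10,
                          max_iter: int = 100) -> np.ndarray:
    """Maximise sum_i case_w_i [ resp_i * eta_i - log(1+e^{eta_i}) ] over
    coefficients, eta = D @ coef, by Newton-Raphson with step-halving.

    ``resp`` may be fractional (the theta-step responds to posterior
    weights).  The score tolerance is scaled by the total case weight so the
    stopping rule is meaningful at any sample size.
    """
    D = np.asarray(D, dtype=float)
    resp = np.asarray(resp, dtype=float).ravel()
    case_w = np.asarray(case_w, dtype=float).ravel()
    coef = np.asarray(start, dtype=float).ravel().copy()
    if coef.shape[0] != D.shape[1]:
        raise ValueError("start length does not match design columns")

    scale = max(1.0, float(np.sum(case_w)))
    score_tol = tol * scale

    def objective(c):
        eta = D @ c
        return float(np.sum(case_w * (resp * eta - log1pexp(eta))))

    obj = objective(coef)
    for it in range(max_iter):
        eta = D @ coef
        mu = special.expit(eta)
        score = D.T @ (case_w * (resp - mu))
        if np.max(np.abs(score)) <= score_tol:
            break
        h = case_w * mu * (1.0 - mu)
        H = D.T @ (D * h[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving: Newton on a concave objective, but guard anyway
        lam, new_obj = 1.0, objective(coef + step)
        while new_obj < obj - 1e-12 and lam > 1e-8:
            lam *= 0.5
            new_obj = objective(coef + lam * step)
        move = lam * step
        coef = coef + move
        obj = new_obj
        if np.max(np.abs(move)) < tol * max(1.0, np.max(np.abs(coef))):
            break
    else:
        raise EstimationError(
            f"inner IRLS failed to converge in {max_iter} iterations")

    # separation check at the optimum
    eta = D @ coef
    if np.max(np.abs(eta)) > _SEPARATION_ETA:
        mu = special.expit(eta)
        h = case_w * mu * (1.0 - mu)
        H = D.T @ (D * h[:, None])
        if np.linalg.cond(H) > 1.0 / _SEPARATION_RCOND:
            raise EstimationError(
                "perfect or quasi-separation: coefficients diverge")
    return coef


def m_step_theta(w, Z, start, controls: EMControls = EMControls()) -> np.ndarray:
    """Update theta: logistic regression of the fractional response w on Z."""
    w = np.asarray(w, dtype=float).ravel()
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("weights w must lie in [0, 1]")
    ones = np.ones_like(w)
    return weighted_logistic_mle(np.asarray(Z, float), w, ones,
                                 start, controls.inner_tol,
                                 controls.inner_max_iter)


def m_step_beta(w, data: Dataset, start,
                controls: EMControls = EMControls()) -> np.ndarray:
    """Update beta: logistic regression of y on X with case weights 1 - w."""
    w = np.asarray(w, dtype=float).ravel()
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("weights w must lie in [0, 1]")
    if np.any(w[data.y == 1.0] != 0.0):
        raise ValueError("w must be exactly 0 wherever y = 1")
    return weighted_logistic_mle(data.X, data.y, 1.0 - w,
                                 start, controls.inner_tol,
                                 controls.inner_max_iter)


def initialize(data: Dataset, controls: EMControls = EMControls()) -> ZIBerParams:
    """Deterministic starting point: beta from an ordinary logistic fit of
    y on X, theta = 0 (inflation probability 1/2 everywhere)."""
    ybar = float(np.mean(data.y))
    if ybar in (0.0, 1.0):
        raise EstimationError("y is constant; the model is not estimable")
    beta0 = weighted_logistic_mle(data.X, data.y, np.ones(data.n),
                                  np.zeros(data.p), controls.inner_tol,
                                  controls.inner_max_iter)
    return ZIBerParams(beta=beta0, theta=np.zeros(data.k))


def _em_map(params: ZIBerParams, data: Dataset,
            controls: EMControls) -> tuple[ZIBerParams, np.ndarray]:
    """One full E-step + M-step update."""
    w = e_step(params, data)
    theta_new = m_step_theta(w, data.Z, params.theta, controls)
    beta_new = m_step_beta(w, data, params.beta, controls)
    return ZIBerParams(beta=beta_new, theta=theta_new), w


def _fit_em_squarem(data: Dataset, controls: EMControls,
                    init: ZIBerParams) -> EMFit:
    """Squared-extrapolation EM (steplength scheme S3).  Candidate steps
    that fail to improve the observed log-likelihood fall back to the
    plain double EM step, so the trace remains monotone."""
    params = init
    ll = observed_loglik(params, data)
    trace: list[float] = []
    converged = False
    maps = 0
    w = None
    while maps < controls.max_iter:
        p1, w = _em_map(params, data, controls)
        maps += 1
        if np.max(np.abs(p1.concat() - params.concat())) < controls.param_tol:
            params = p1
            trace.append(observed_loglik(params, data))
            converged = True
            break
        p2, w = _em_map(p1, data, controls)
        maps += 1
        x0, x1, x2 = params.concat(), p1.concat(), p2.concat()
        r = x1 - x0
        v = (x2 - x1) - r
        vnorm = float(np.sqrt(v @ v))
        accepted = None
        if vnorm > 0.0:
            alpha = -float(np.sqrt(r @ r)) / vnorm
            xp = x0 - 2.0 * alpha * r + alpha * alpha * v
            cand = ZIBerParams(beta=xp[:data.p], theta=xp[data.p:])
            try:
                p3, w3 = _em_map(cand, data, controls)
                ll3 = observed_loglik(p3, data)
                if ll3 >= ll - 1e-10:
                    accepted, ll, w = p3, ll3, w3
                maps += 1
            except EstimationError:
                pass
        if accepted is None:
            accepted = p2
            ll = observed_loglik(p2, data)
        trace.append(ll)
        if np.max(np.abs(accepted.concat() - x2)) < controls.param_tol \
                and np.max(np.abs(x2 - x1)) < controls.param_tol:
            params = accepted
            converged = True
            break
        params = accepted
    return EMFit(params=params, converged=converged, n_iter=maps,
                 loglik_trace=np.asarray(trace), weights=w)


def fit_em(data: Dataset, controls: EMControls = EMControls(),
           init: ZIBerParams | None = None) -> EMFit:
    """Run the EM loop until the stopping rule fires.

    Stops with ``converged=True`` when the largest absolute coefficient
    change between adjacent iterations falls below ``controls.param_tol``,
    or with ``converged=False`` after ``controls.max_iter`` iterations.
    ``loglik_trace`` holds the observed log-likelihood after each iteration
    and is non-decreasing (a property of EM, asserted by the test suite).
    """
    if init is None:
        init = initialize(data, controls)
    else:
        init.check_matches(data)

    if controls.accelerate:
        return _fit_em_squarem(data, controls, init)

    params = init
    trace: list[float] = []
    converged = False
    n_iter = 0
    w = None
    for h in range(controls.max_iter):
        try:
            w = e_step(params, data)
            theta_new = m_step_theta(w, data.Z, params.theta, controls)
            beta_new = m_step_beta(w, data, params.beta, controls)
        except EstimationError as err:
            raise EstimationError(f"EM failed at iteration {h + 1}: {err}") from err
        new_params = ZIBerParams(beta=beta_new, theta=theta_new)
        trace.append(observed_loglik(new_params, data))
        n_iter = h + 1
        delta_max = np.max(np.abs(new_params.concat() - params.concat()))
        params = new_params
        if delta_max < controls.param_tol:
            converged = True
            break
    return EMFit(params=params, converged=converged, n_iter=n_iter,
                 loglik_trace=np.asarray(trace), weights=w)
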
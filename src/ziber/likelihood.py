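"""Link functions and likelihood quantities of the zero-inflated Bernoulli model.

All routines are pure and vectorised.  The observed-data log-likelihood is
the Bernoulli(pi) log-likelihood with pi = (1 - delta) * p; the complete-data
log-likelihood splits into two weighted logistic terms, one per component,
which is what makes the EM algorithm's M-step a pair of weighted logistic
regressions.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .data import Dataset, Probabilities, ZIBerParams

__all__ = [
    "sigmoid",
    "log1pexp",
    "event_probabilities",
    "observed_loglik",
    "complete_loglik_theta",
    "complete_loglik_beta",
]


def sigmoid(u):
    """Numerically stable logistic function 1 / (1 + e^{-u}).

    Accepts scalars or arrays; +/-inf map to 1/0.  Non-numeric input raises
    ``TypeError``/``ValueError``.
    """
    u = np.asarray(u, dtype=float)
    out = special.expit(u)
    return float(out) if out.ndim == 0 else out


def log1pexp(u):
    """log(1 + e^u) without overflow (softplus)."""
    u = np.asarray(u, dtype=float)
    out = np.logaddexp(0.0, u)
    return float(out) if out.ndim == 0 else out


def event_probabilities(params: ZIBerParams, data: Dataset) -> Probabilities:
    """Per-observation p, delta and pi under the given coefficients."""
    params.check_matches(data)
    p = special.expit(data.X @ params.beta)
    delta = special.expit(data.Z @ params.theta)
    return Probabilities(p=p, delta=delta)


def observed_loglik(params: ZIBerParams, data: Dataset) -> float:
    """Observed-data log-likelihood: sum of Bernoulli(pi) log-terms.

    Returns -inf when some observation has likelihood zero (pi exactly 0
    with y=1, or pi exactly 1 with y=0); never raises for that case.
    """
    params.check_matches(data)
    eta_x = data.X @ params.beta
    eta_z = data.Z @ params.theta
    # log pi = log p + log(1-delta), both as stable log-sigmoids
    log_pi = special.log_expit(eta_x) + special.log_expit(-eta_z)
    pi = np.exp(log_pi)
    y = data.y
    with np.errstate(divide="ignore"):
        log_1mpi = np.log1p(-pi)
    terms = np.where(y == 1.0, log_pi, log_1mpi)
    return float(np.sum(terms))


def complete_loglik_theta(theta, Z, w) -> float:
    """Inflation-component complete-data log-likelihood
    sum_i [ w_i * z_i'theta - log(1 + e^{z_i'theta}) ].

    ``w`` are posterior structural-zero weights in [0, 1].
    """
    theta = np.asarray(theta, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("weights w must lie in [0, 1]")
    eta = Z @ theta
    return float(np.sum(w * eta - log1pexp(eta)))


def complete_loglik_beta(beta, data: Dataset, w) -> float:
    """Event-component complete-data log-likelihood
    sum_i (1 - w_i) * [ y_i * x_i'beta - log(1 + e^{x_i'beta}) ]."""
    beta = np.asarray(beta, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("weights w must lie in [0, 1]")
    eta = data.X @ beta
    return float(np.sum((1.0 - w) * (data.y * eta - log1pexp(eta))))
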
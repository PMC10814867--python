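"""Core data containers for the zero-inflated Bernoulli regression model.

The model describes a binary outcome ``y`` through two logistic components:
an *event* model ``logit(p_i) = x_i' beta`` on the design matrix ``X`` and a
*zero-inflation* model ``logit(delta_i) = z_i' theta`` on ``Z``.  An
observation is a structural zero (forced ``y=0``) with probability
``delta_i``; otherwise ``y`` is Bernoulli with probability ``p_i``, so the
marginal event probability is ``pi_i = (1 - delta_i) * p_i``.

Both design matrices are required to carry an explicit leading intercept
column of ones; higher-level constructors (``ZIBer.from_dataframe``, the
CSV reader) prepend it for you.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt


class EstimationError(RuntimeError):
    """Raised when maximum-likelihood estimation fails (separation,
    non-convergence of an inner optimizer, or a degenerate outcome)."""


def _as_2d_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class Dataset:
    """Outcome vector plus the two design matrices of the model.

    Parameters
    ----------
    y : (n,) array of 0/1
    X : (n, p) event-model design; first column must be all ones.
    Z : (n, k) zero-inflation design; first column must be all ones.
    x_names, z_names : optional column labels (intercept included).
    """

    y: npt.NDArray[np.float64]
    X: npt.NDArray[np.float64]
    Z: npt.NDArray[np.float64]
    x_names: tuple[str, ...] | None = None
    z_names: tuple[str, ...] | None = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        X = _as_2d_float(self.X, "X")
        Z = _as_2d_float(self.Z, "Z")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite entries")
        if not np.all((y == 0.0) | (y == 1.0)):
            bad = np.unique(y[(y != 0.0) & (y != 1.0)])[:5]
            raise ValueError(f"y must be binary 0/1; found values {bad}")
        n = y.shape[0]
        if X.shape[0] != n or Z.shape[0] != n:
            raise ValueError(
                f"row mismatch: y has {n}, X has {X.shape[0]}, Z has {Z.shape[0]}"
            )
        if not np.all(X[:, 0] == 1.0):
            raise ValueError("first column of X must be an all-ones intercept")
        if not np.all(Z[:, 0] == 1.0):
            raise ValueError("first column of Z must be an all-ones intercept")
        for attr, names, ncol in (
            ("x_names", self.x_names, X.shape[1]),
            ("z_names", self.z_names, Z.shape[1]),
        ):
            if names is not None and len(names) != ncol:
                raise ValueError(f"{attr} has {len(names)} labels for {ncol} columns")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        if self.x_names is not None:
            object.__setattr__(self, "x_names", tuple(self.x_names))
        if self.z_names is not None:
            object.__setattr__(self, "z_names", tuple(self.z_names))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return self.Z.shape[1]

    def subset(self, idx) -> "Dataset":
        """Row subset (used by train/test splitting)."""
        return Dataset(self.y[idx], self.X[idx], self.Z[idx],
                       self.x_names, self.z_names)


@dataclass(frozen=True)
class ZIBerParams:
    """Coefficient vectors of the two logistic components."""

    beta: npt.NDArray[np.float64]
    theta: npt.NDArray[np.float64]

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float).ravel()
        theta = np.asarray(self.theta, dtype=float).ravel()
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(theta))):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "theta", theta)

    def check_matches(self, data: Dataset) -> None:
        if self.beta.shape[0] != data.p:
            raise ValueError(
                f"beta has length {self.beta.shape[0]}, X has {data.p} columns")
        if self.theta.shape[0] != data.k:
            raise ValueError(
                f"theta has length {self.theta.shape[0]}, Z has {data.k} columns")

    def concat(self) -> np.ndarray:
        return np.concatenate([self.beta, self.theta])


@dataclass(frozen=True)
class Probabilities:
    """Per-observation event (p), inflation (delta) and marginal (pi)
    probabilities, with the identity pi = (1 - delta) * p."""

    p: npt.NDArray[np.float64]
    delta: npt.NDArray[np.float64]
    pi: npt.NDArray[np.float64] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float).ravel()
        delta = np.asarray(self.delta, dtype=float).ravel()
        pi = (1.0 - delta) * p if self.pi is None else np.asarray(self.pi, float).ravel()
        if not np.allclose(pi, (1.0 - delta) * p, rtol=0.0, atol=1e-12):
            raise ValueError("pi must equal (1 - delta) * p elementwise")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "pi", pi)
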
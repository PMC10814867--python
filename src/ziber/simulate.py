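"""Synthetic zero-inflated Bernoulli samples with the latent truth exposed.

The default configuration reproduces the benchmark design used throughout
the package's simulation studies: an event model with a standard-normal and
a Bernoulli(0.75) covariate and coefficients (-1, 1, -2), and an inflation
model with a Weibull(shape 3.6, scale 1) covariate and coefficients
(-1, 2).  Under these defaults the marginal event rate lands in the low
single-digit percent range — a heavily imbalanced outcome.

Two generation schemes are available and are distributionally equivalent:

* ``indicator`` (default): draw u ~ Uniform(0,1); if u <= delta the
  observation is a structural zero (y = 0), otherwise y ~ Bernoulli(p).
  This records which zeros are structural.
* ``marginal``: draw y ~ Bernoulli(pi) directly with pi = (1 - delta) p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .data import Dataset

__all__ = ["SimulationConfig", "SimulatedSample", "simulate_dataset"]

X_NAMES = ("intercept", "x2", "x3")
Z_NAMES = ("intercept", "z2")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the zero-inflated benchmark generator.

    beta : event-model coefficients (intercept, x2, x3).
    theta : inflation-model coefficients (intercept, z2).
    x3_prob : success probability of the binary covariate x3.
    weibull_shape, weibull_scale : z2 ~ Weibull(shape, scale).
    scheme : "indicator" (latent truth recorded) or "marginal".
    """

    n: int = 5000
    beta: tuple[float, ...] = (-1.0, 1.0, -2.0)
    theta: tuple[float, ...] = (-1.0, 2.0)
    x3_prob: float = 0.75
    weibull_shape: float = 3.6
    weibull_scale: float = 1.0
    seed: int = 0
    scheme: str = "indicator"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.beta) != 3 or len(self.theta) != 2:
            raise ValueError("beta must have length 3 and theta length 2")
        if not (0.0 < self.x3_prob < 1.0):
            raise ValueError("x3_prob must lie in (0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if self.scheme not in ("indicator", "marginal"):
            raise ValueError("scheme must be 'indicator' or 'marginal'")


@dataclass(frozen=True)
class SimulatedSample:
    """A generated dataset plus the latent quantities used to build it."""

    data: Dataset
    structural_zero: np.ndarray | None  # None under the marginal scheme
    p: np.ndarray
    delta: np.ndarray
    pi: np.ndarray

    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({
            "y": self.data.y.astype(int),
            "x2": self.data.X[:, 1],
            "x3": self.data.X[:, 2].astype(int),
            "z2": self.data.Z[:, 1],
        })
        if include_latent and self.structural_zero is not None:
            df["structural_zero"] = self.structural_zero.astype(int)
        return df


def simulate_dataset(config: SimulationConfig) -> SimulatedSample:
    """Draw one sample, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    x2 = rng.standard_normal(n)
    x3 = (rng.random(n) < config.x3_prob).astype(float)
    z2 = config.weibull_scale * rng.weibull(config.weibull_shape, size=n)

    X = np.column_stack([np.ones(n), x2, x3])
    Z = np.column_stack([np.ones(n), z2])
    beta = np.asarray(config.beta, dtype=float)
    theta = np.asarray(config.theta, dtype=float)
    p = special.expit(X @ beta)
    delta = special.expit(Z @ theta)
    pi = (1.0 - delta) * p

    if config.scheme == "indicator":
        u = rng.random(n)
        structural = u <= delta
        y = np.where(structural, 0.0, (rng.random(n) < p).astype(float))
        struct_out = structural
    else:
        y = (rng.random(n) < pi).astype(float)
        struct_out = None

    data = Dataset(y=y, X=X, Z=Z, x_names=X_NAMES, z_names=Z_NAMES)
    return SimulatedSample(data=data, structural_zero=struct_out,
                           p=p, delta=delta, pi=pi)
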
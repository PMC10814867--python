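"""The ZIBer model class and its results object.

Usage mirrors statsmodels: construct the model from data, call ``fit()``,
and work with the returned :class:`ZIBerResults`::

    from ziber import ZIBer
    model = ZIBer.from_dataframe(df, outcome="y", x_cols=["x2", "x3"],
                                 z_cols=["z2"])
    res = model.fit()
    print(res.summary())
    labels = res.predict_label(cut=res.find_cut())

The model is a two-component mixture for a binary outcome: with probability
``delta_i`` (logistic in Z) the outcome is a structural zero, otherwise it
is Bernoulli with probability ``p_i`` (logistic in X).  ``fit`` maximises
the observed-data likelihood by EM; standard errors are not computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify
from .data import Dataset, EstimationError, ZIBerParams
from .em import EMControls, EMFit, fit_em
from .likelihood import event_probabilities, observed_loglik

__all__ = ["ZIBer", "ZIBerResults"]


class ZIBer:
    """Zero-inflated Bernoulli regression model.

    Parameters
    ----------
    y, X, Z : outcome and design matrices; X and Z must carry a leading
        all-ones intercept column (``from_dataframe`` adds it for you).
    x_names, z_names : optional column labels.
    """

    def __init__(self, y, X, Z, x_names=None, z_names=None):
        self.data = Dataset(y=np.asarray(y, float), X=X, Z=Z,
                            x_names=x_names, z_names=z_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       x_cols: list[str], z_cols: list[str],
                       add_intercept: bool = True) -> "ZIBer":
        """Build the model from a DataFrame; prepends intercept columns."""
        missing = [c for c in [outcome, *x_cols, *z_cols] if c not in df.columns]
        if missing:
            raise KeyError(f"columns not found: {missing}")
        if outcome in x_cols or outcome in z_cols:
            raise ValueError("outcome column cannot appear among covariates")
        y = df[outcome].to_numpy(dtype=float)
        X = df[x_cols].to_numpy(dtype=float)
        Z = df[z_cols].to_numpy(dtype=float)
        x_names, z_names = list(x_cols), list(z_cols)
        if add_intercept:
            X = np.column_stack([np.ones(len(df)), X])
            Z = np.column_stack([np.ones(len(df)), Z])
            x_names = ["intercept", *x_names]
            z_names = ["intercept", *z_names]
        return cls(y, X, Z, x_names=x_names, z_names=z_names)

    @classmethod
    def from_dataset(cls, data: Dataset) -> "ZIBer":
        obj = cls.__new__(cls)
        obj.data = data
        return obj

    def loglike(self, params: ZIBerParams) -> float:
        """Observed-data log-likelihood at ``params``."""
        return observed_loglik(params, self.data)

    def fit(self, controls: EMControls | None = None,
            start: ZIBerParams | None = None) -> "ZIBerResults":
        """Estimate (beta, theta) by EM; see :func:`ziber.em.fit_em`.

        Raises :class:`~ziber.data.EstimationError` when y is constant or an
        M-step encounters separation.
        """
        controls = controls or EMControls()
        emfit = fit_em(self.data, controls, init=start)
        return ZIBerResults(self, emfit, controls)


class ZIBerResults:
    """Fitted ZIBer model: coefficients, likelihood trace, prediction and
    cut-point selection."""

    def __init__(self, model: ZIBer, emfit: EMFit, controls: EMControls):
        self.model = model
        self.params = emfit.params
        self.converged = emfit.converged
        self.n_iter = emfit.n_iter
        self.loglik_trace = emfit.loglik_trace
        self.posterior_weights = emfit.weights
        self.controls = controls
        self.cut: float | None = None
        self.train_metrics: tuple[float, float, float] | None = None

    @property
    def beta(self) -> np.ndarray:
        return self.params.beta

    @property
    def theta(self) -> np.ndarray:
        return self.params.theta

    @property
    def llf(self) -> float:
        return float(self.loglik_trace[-1])

    def predict(self, data: Dataset | None = None, which: str = "p") -> np.ndarray:
        """Predicted probabilities on ``data`` (default: training data).

        ``which`` selects the event probability ``"p"`` (the quantity the
        cut point thresholds by default), the inflation probability
        ``"delta"``, or the marginal event probability ``"pi"``.
        """
        data = data or self.model.data
        probs = event_probabilities(self.params, data)
        try:
            return getattr(probs, which)
        except AttributeError:
            raise ValueError("which must be 'p', 'delta' or 'pi'") from None

    def find_cut(self, data: Dataset | None = None, which: str = "p",
                 grid=classify.DEFAULT_CUT_GRID) -> float:
        """Grid-search the cut point minimising the misclassification rate
        on ``data`` (default: the training fold); stores it on the results
        object and records the training metrics at that cut."""
        data = data or self.model.data
        prob = self.predict(data, which=which)
        cut = classify.best_cut(prob, data.y, grid)
        labels = classify.predict_label(prob, cut)
        self.cut = cut
        self.train_metrics = classify.metrics(
            classify.confusion_counts(data.y, labels))
        return cut

    def predict_label(self, data: Dataset | None = None, cut: float | None = None,
                      which: str = "p") -> np.ndarray:
        """Binary labels: 1 iff the selected probability >= cut."""
        if cut is None:
            if self.cut is None:
                raise ValueError("no cut point: pass cut= or call find_cut()")
            cut = self.cut
        return classify.predict_label(self.predict(data, which=which), cut)

    def summary(self) -> str:
        """Plain-text coefficient table in the style of statsmodels."""
        d = self.model.data
        x_names = d.x_names or [f"x{j + 1}" for j in range(d.p)]
        z_names = d.z_names or [f"z{j + 1}" for j in range(d.k)]
        lines = [
            "Zero-Inflated Bernoulli Regression (EM)",
            "=" * 46,
            f"No. observations: {d.n:>8d}    converged: {self.converged}",
            f"EM iterations:    {self.n_iter:>8d}    log-likelihood: {self.llf:.4f}",
            "-" * 46,
            "Event model (logit p)         coef",
        ]
        for name, b in zip(x_names, self.beta):
            lines.append(f"  {name:<24s}{b:>12.4f}")
        lines.append("Zero-inflation model (logit delta)")
        for name, t in zip(z_names, self.theta):
            lines.append(f"  {name:<24s}{t:>12.4f}")
        if self.cut is not None:
            acc, sens, spec = self.train_metrics
            lines += [
                "-" * 46,
                f"cut point: {self.cut:.2f}   train accuracy: {acc:.4f}",
                f"train sensitivity: {sens:.4f}   train specificity: {spec:.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)
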
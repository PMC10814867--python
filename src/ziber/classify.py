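"""Min-max scaling, cut-point search and classification metrics.

The classifier thresholds a fitted probability at a cut point chosen by a
global grid search minimising the training misclassification rate.  With
heavily imbalanced outcomes, accuracy alone hides the minority class, so
sensitivity (true-positive rate) and specificity (true-negative rate) are
reported alongside it; metrics with an empty denominator are returned as
NaN rather than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset

__all__ = ["ScalingSpec", "ConfusionCounts", "scale_fit", "scale_apply",
           "predict_label", "confusion_counts", "metrics", "best_cut",
           "DEFAULT_CUT_GRID"]

#: 0.01-step grid; every reported cut has two decimals.
DEFAULT_CUT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass(frozen=True)
class ScalingSpec:
    """Training-fold minima/maxima per design column (intercepts exempt).

    Applying to unseen data may produce values outside [0, 1]; that is the
    intended contract (no re-fitting on test data).
    """

    x_min: np.ndarray
    x_max: np.ndarray
    z_min: np.ndarray
    z_max: np.ndarray


def _column_minmax(M: np.ndarray, names, label: str):
    mins = M.min(axis=0)
    maxs = M.max(axis=0)
    const = (maxs == mins) & (np.arange(M.shape[1]) > 0)
    if np.any(const):
        j = int(np.flatnonzero(const)[0])
        name = names[j] if names is not None else f"column {j}"
        raise ValueError(f"constant {label} column cannot be min-max scaled: {name}")
    return mins, maxs


def scale_fit(data: Dataset) -> ScalingSpec:
    """Learn per-column min/max from (training) data."""
    x_min, x_max = _column_minmax(data.X, data.x_names, "X")
    z_min, z_max = _column_minmax(data.Z, data.z_names, "Z")
    return ScalingSpec(x_min, x_max, z_min, z_max)


def _apply(M: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    out = M.copy()
    rng = maxs - mins
    cols = np.arange(1, M.shape[1])  # intercept passes through
    out[:, cols] = (M[:, cols] - mins[cols]) / rng[cols]
    return out


def scale_apply(spec: ScalingSpec, data: Dataset) -> Dataset:
    """Transform every non-intercept column with the stored training
    min/max: x* = (x - min) / (max - min)."""
    return Dataset(data.y, _apply(data.X, spec.x_min, spec.x_max),
                   _apply(data.Z, spec.z_min, spec.z_max),
                   data.x_names, data.z_names)


def predict_label(prob, cut: float) -> np.ndarray:
    """Label 1 iff prob_i >= cut (the boundary counts as positive)."""
    if not 0.0 <= cut <= 1.0:
        raise ValueError("cut must lie in [0, 1]")
    return (np.asarray(prob, dtype=float) >= cut).astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where the denominator is
    zero, so undefined values stay visible downstream."""
    acc = (c.TP + c.TN) / c.total if c.total else float("nan")
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    return acc, sens, spec


def best_cut(prob, y, grid=DEFAULT_CUT_GRID) -> float:
    """Grid value minimising the misclassification rate of thresholding
    ``prob`` against ``y``; ties resolve to the smallest cut."""
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("cut grid must be non-empty")
    # errors(cut) = #(prob >= cut & y==0) + #(prob < cut & y==1), all cuts at once
    pred = prob[:, None] >= grid[None, :]
    errors = np.sum(pred != (y[:, None] == 1.0), axis=0)
    return float(grid[int(np.argmin(errors))])
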
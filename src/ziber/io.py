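"""Tabular I/O and model serialization for the command-line workflow.

A fitted model travels as a JSON document holding the coefficient vectors
with their column names, the min-max scaling spec learned on the training
data, the chosen cut point, and which probability the cut thresholds —
enough to predict on raw (unscaled) data with no other state.

Dummy encoding of categorical covariates is deliberately left to the user:
``dummy_encode`` is provided as an explicit helper and is never applied
silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ScalingSpec
from .data import Dataset, ZIBerParams

__all__ = ["ColumnSpec", "read_dataset", "write_dataset",
           "model_to_json", "model_from_json", "dummy_encode"]

logger = logging.getLogger("ziber.io")


@dataclass(frozen=True)
class ColumnSpec:
    """Which columns of a table play which role.

    X and Z lists may overlap; the outcome may appear in neither.
    """

    outcome: str
    x_cols: tuple[str, ...]
    z_cols: tuple[str, ...]

    def __post_init__(self):
        if self.outcome in self.x_cols or self.outcome in self.z_cols:
            raise ValueError("outcome column cannot appear among covariates")
        if not self.x_cols or not self.z_cols:
            raise ValueError("x_cols and z_cols must be non-empty")
        object.__setattr__(self, "x_cols", tuple(self.x_cols))
        object.__setattr__(self, "z_cols", tuple(self.z_cols))


def read_dataset(path, spec: ColumnSpec, sep: str = ",") -> Dataset:
    """Read a CSV/TSV into a :class:`Dataset`, prepending intercepts.

    Rows with missing values in any used column are dropped with a logged
    count.  A non-binary outcome or a missing column raises ``ValueError``
    / ``KeyError`` naming the offender.
    """
    df = pd.read_csv(path, sep=sep)
    used = [spec.outcome, *dict.fromkeys([*spec.x_cols, *spec.z_cols])]
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise KeyError(f"columns not found in {path}: {missing}")
    before = len(df)
    df = df.dropna(subset=used)
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values in used columns", dropped)
    y = df[spec.outcome].to_numpy(dtype=float)
    bad = np.unique(y[(y != 0.0) & (y != 1.0)])
    if bad.size:
        raise ValueError(
            f"outcome column {spec.outcome!r} is not binary; found {bad[:5]}")
    n = len(df)
    X = np.column_stack([np.ones(n), df[list(spec.x_cols)].to_numpy(float)])
    Z = np.column_stack([np.ones(n), df[list(spec.z_cols)].to_numpy(float)])
    return Dataset(y=y, X=X, Z=Z,
                   x_names=("intercept", *spec.x_cols),
                   z_names=("intercept", *spec.z_cols))


def write_dataset(data: Dataset, path) -> None:
    """Write the used columns back to CSV (17 significant digits, so a
    read/write round trip is lossless)."""
    cols = {"y": data.y.astype(int)}
    x_names = data.x_names or [f"x{j + 1}" for j in range(data.p)]
    z_names = data.z_names or [f"z{j + 1}" for j in range(data.k)]
    for j in range(1, data.p):
        cols[x_names[j]] = data.X[:, j]
    for j in range(1, data.k):
        name = z_names[j]
        if name not in cols:
            cols[name] = data.Z[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def model_to_json(params: ZIBerParams, spec: ColumnSpec,
                  scaling: ScalingSpec | None, cut: float | None,
                  threshold_on: str = "p",
                  extra: dict | None = None) -> str:
    doc = {
        "model": "ziber",
        "outcome": spec.outcome,
        "x_cols": list(spec.x_cols),
        "z_cols": list(spec.z_cols),
        "beta": params.beta.tolist(),
        "theta": params.theta.tolist(),
        "scaling": None if scaling is None else {
            "x_min": scaling.x_min.tolist(), "x_max": scaling.x_max.tolist(),
            "z_min": scaling.z_min.tolist(), "z_max": scaling.z_max.tolist(),
        },
        "cut": cut,
        "threshold_on": threshold_on,
    }
    if extra:
        doc.update(extra)
    return json.dumps(doc, indent=2)


def model_from_json(text: str):
    """Inverse of :func:`model_to_json`; returns
    (params, spec, scaling, cut, threshold_on)."""
    doc = json.loads(text)
    params = ZIBerParams(beta=np.asarray(doc["beta"], float),
                         theta=np.asarray(doc["theta"], float))
    spec = ColumnSpec(outcome=doc["outcome"], x_cols=tuple(doc["x_cols"]),
                      z_cols=tuple(doc["z_cols"]))
    scaling = None
    if doc.get("scaling") is not None:
        s = doc["scaling"]
        scaling = ScalingSpec(np.asarray(s["x_min"], float),
                              np.asarray(s["x_max"], float),
                              np.asarray(s["z_min"], float),
                              np.asarray(s["z_max"], float))
    return params, spec, scaling, doc.get("cut"), doc.get("threshold_on", "p")


def dummy_encode(df: pd.DataFrame, column: str, codes: dict) -> pd.DataFrame:
    """Explicit dummy encoding: map each level of ``column`` to a tuple of
    0/1 indicator values via ``codes`` (e.g. ``{1: (1, 0), 2: (0, 1),
    3: (1, 1)}``), producing columns ``column_d1, column_d2, ...``."""
    width = len(next(iter(codes.values())))
    mapped = df[column].map(lambda v: codes[v])
    out = df.copy()
    for j in range(width):
        out[f"{column}_d{j + 1}"] = mapped.map(lambda t, j=j: t[j])
    return out
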
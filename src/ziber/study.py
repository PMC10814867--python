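"""Repeated train/test evaluation of the ZIBer classifier.

Protocol per repetition: obtain a dataset (a fresh simulated sample, or a
re-split of a fixed dataset), hold out a test fraction, min-max scale using
the training fold only, fit the ZIBer model by EM on the training fold,
grid-search the cut point on the training fold, then score the untouched
test fold.  Accuracy, sensitivity and specificity are averaged across
repetitions; repetitions where a metric is undefined (empty denominator)
are excluded from that metric's mean with a reported count, and repetitions
where estimation fails are excluded entirely.

Seeding: repetition ``r`` of a study with master seed ``s`` draws its
simulation and split seeds from ``numpy.random.SeedSequence([s, r, 0])``
and ``([s, r, 1])`` — reproducible and independent across repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

from . import classify
from .data import Dataset, EstimationError
from .em import EMControls
from .model import ZIBer
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["StudyConfig", "MetricSummary", "train_test_split", "run_study"]

logger = logging.getLogger("ziber.study")

_METRICS = ("accuracy", "sensitivity", "specificity")


def _derived_seed(master: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


def train_test_split(data: Dataset, fraction: float = 0.8,
                     stratified: bool = False, seed: int = 0):
    """Disjoint, exhaustive train/test partition of the rows.

    When ``stratified``, the positive-class proportion is preserved in both
    folds (both classes must have at least 2 members).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    strat = None
    if stratified:
        counts = np.bincount(data.y.astype(int), minlength=2)
        if counts.min() < 2:
            raise ValueError(
                "stratified split impossible: a class has fewer than 2 members")
        strat = data.y
    idx_train, idx_test = _sk_split(np.arange(data.n), train_size=fraction,
                                    stratify=strat, random_state=seed)
    return data.subset(np.sort(idx_train)), data.subset(np.sort(idx_test))


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a repeated train/test study.

    Either ``simulation`` (a fresh sample per repetition) or ``dataset``
    (re-split per repetition) must be given.  ``threshold_on`` selects the
    probability that the cut point thresholds: the event probability "p"
    (default) or the marginal probability "pi".
    """

    repetitions: int = 1000
    train_fraction: float = 0.8
    stratified: bool = False
    cut_grid: np.ndarray = field(default_factory=lambda: classify.DEFAULT_CUT_GRID)
    em_controls: EMControls = field(default_factory=EMControls)
    simulation: SimulationConfig | None = None
    dataset: Dataset | None = None
    scale: bool = True
    threshold_on: str = "p"
    seed: int = 0

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie strictly in (0, 1)")
        if (self.simulation is None) == (self.dataset is None):
            raise ValueError("give exactly one of simulation= or dataset=")
        if self.threshold_on not in ("p", "pi"):
            raise ValueError("threshold_on must be 'p' or 'pi'")


@dataclass(frozen=True)
class MetricSummary:
    """Means and standard deviations of the three metrics across
    repetitions, with per-repetition rows retrievable via ``records``."""

    mean: dict[str, float]
    std: dict[str, float]
    n_undefined: dict[str, int]
    n_failed: int
    records: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "mean": dict(self.mean),
            "std": dict(self.std),
            "n_undefined": dict(self.n_undefined),
            "n_failed": self.n_failed,
            "repetitions": int(len(self.records)),
        }


def _one_repetition(config: StudyConfig, rep: int) -> dict:
    if config.simulation is not None:
        sim_cfg = SimulationConfig(
            **{**config.simulation.__dict__,
               "seed": _derived_seed(config.seed, rep, 0)})
        data = simulate_dataset(sim_cfg).data
    else:
        data = config.dataset
    split_seed = _derived_seed(config.seed, rep, 1)
    train, test = train_test_split(data, config.train_fraction,
                                   config.stratified, split_seed)
    if config.scale:
        spec = classify.scale_fit(train)
        train = classify.scale_apply(spec, train)
        test = classify.scale_apply(spec, test)

    res = ZIBer.from_dataset(train).fit(config.em_controls)
    cut = res.find_cut(which=config.threshold_on, grid=config.cut_grid)
    labels = res.predict_label(test, cut=cut, which=config.threshold_on)
    acc, sens, spec_ = classify.metrics(
        classify.confusion_counts(test.y, labels))
    return {"rep": rep, "accuracy": acc, "sensitivity": sens,
            "specificity": spec_, "cut": cut, "n_iter": res.n_iter,
            "converged": res.converged}


def run_study(config: StudyConfig) -> MetricSummary:
    """Run the repeated protocol and summarise the test-fold metrics."""
    rows = []
    n_failed = 0
    for rep in range(config.repetitions):
        try:
            rows.append(_one_repetition(config, rep))
        except (EstimationError, ValueError) as err:
            n_failed += 1
            logger.warning("repetition %d excluded: %s", rep, err)
    records = pd.DataFrame(rows)
    if records.empty:
        raise EstimationError("every repetition failed")
    mean, std, n_undef = {}, {}, {}
    for m in _METRICS:
        vals = records[m].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        n_undef[m] = int(np.isnan(vals).sum())
        mean[m] = float(np.mean(defined)) if defined.size else float("nan")
        std[m] = float(np.std(defined, ddof=1)) if defined.size > 1 else float("nan")
        if n_undef[m]:
            logger.info("%s undefined in %d repetitions", m, n_undef[m])
    return MetricSummary(mean=mean, std=std, n_undefined=n_undef,
                         n_failed=n_failed, records=records)
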
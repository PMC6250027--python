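"""Bagged decision-tree ensemble (majority vote) and confusion metrics.

Nucleus class frequencies are heavily skewed — malignant nuclei are rare
against an abundant benign background — and bootstrap-aggregated trees
are a standard, robust choice in that regime.  One hundred unpruned CART
trees are each fit on an n-out-of-n bootstrap resample of the training
rows (restricted to the selected feature columns); prediction is by
majority vote with exact ties broken toward malignant, the safer call in
a screening setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "EnsembleConfig",
    "EnsembleModel",
    "ConfusionCounts",
    "MetricsReport",
    "train_ecbdt",
    "predict",
    "compute_metrics",
    "counts_from_labels",
]

POSITIVE = "malignant"
NEGATIVE = "benign"


@dataclass(frozen=True)
class EnsembleConfig:
    n_trees: int = 100
    seed: int = 0
    n_folds: int = 5


@dataclass
class EnsembleModel:
    """Trained bagged-tree ensemble plus its cross-validation report."""

    trees: list[DecisionTreeClassifier]
    selected: list[str]
    seed: int
    cv_report: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("all-zero confusion counts")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix metrics as percentages; recall equals sensitivity."""

    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f_score: float
    accuracy: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "accuracy": self.accuracy,
        }


def _fit_bagged(x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator):
    trees = []
    n = len(y)
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31 - 1)))
        tree.fit(x[idx], y[idx])
        trees.append(tree)
    return trees


def _vote(trees, x: np.ndarray) -> np.ndarray:
    """Majority vote over tree predictions; exact ties go to malignant."""
    votes = np.zeros(len(x), dtype=int)  # count of malignant votes
    for tree in trees:
        votes += tree.predict(x) == POSITIVE
    half = len(trees) / 2.0
    return np.where(votes >= half, POSITIVE, NEGATIVE)


def train_ecbdt(
    table: pd.DataFrame, selected: list[str], cfg: EnsembleConfig = EnsembleConfig()
) -> EnsembleModel:
    """Train the ensemble and produce a stratified k-fold CV report.

    The CV report scores a freshly bagged ensemble within each training
    fold; the returned model is trained on all rows.  Raises on
    single-class data or on selected columns missing from the table.
    """
    missing = [c for c in selected if c not in table.columns]
    if missing:
        raise ValueError(f"selected columns not in table: {missing}")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    x = table[list(selected)].to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        rng = np.random.default_rng((cfg.seed * 1000 + fold) % (2**31 - 1))
        trees = _fit_bagged(x[tr], y[tr], cfg.n_trees, rng)
        pred = _vote(trees, x[te])
        counts = counts_from_labels(y[te], pred)
        rows.append({"fold": fold, **compute_metrics(counts).as_dict()})
    report = pd.DataFrame(rows)

    rng = np.random.default_rng(cfg.seed)
    trees = _fit_bagged(x, y, cfg.n_trees, rng)
    return EnsembleModel(trees=trees, selected=list(selected), seed=cfg.seed, cv_report=report)


def predict(model: EnsembleModel, rows: pd.DataFrame) -> np.ndarray:
    """Majority-vote labels for new rows (must carry the model's columns)."""
    missing = [c for c in model.selected if c not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing model columns: {missing}")
    x = rows[model.selected].to_numpy(dtype=float)
    return _vote(model.trees, x)


def counts_from_labels(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    return ConfusionCounts(
        tp=int(np.sum((truth == POSITIVE) & (pred == POSITIVE))),
        fp=int(np.sum((truth == NEGATIVE) & (pred == POSITIVE))),
        tn=int(np.sum((truth == NEGATIVE) & (pred == NEGATIVE))),
        fn=int(np.sum((truth == POSITIVE) & (pred == NEGATIVE))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision, recall, F-score, accuracy (%).

    A ratio with zero denominator is reported as 0 and named in the
    ``undefined`` flag tuple (with a warning).
    """
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return 100.0 * num / den

    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = sens
    if prec + recall == 0:
        undefined.append("f_score")
        f_score = 0.0
    else:
        f_score = 2.0 * prec * recall / (prec + recall)
    total = counts.tp + counts.fp + counts.tn + counts.fn
    acc = 100.0 * (counts.tp + counts.tn) / total
    if undefined:
        warnings.warn(f"metrics undefined (zero denominator): {undefined}", stacklevel=2)
    return MetricsReport(
        sensitivity=sens, specificity=spec, precision=prec,
        recall=recall, f_score=f_score, accuracy=acc, undefined=tuple(undefined),
    )
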
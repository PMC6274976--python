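"""Classifier contracts, stratified k-fold cross-validation and the four
performance measurements (SN, SP, ACC, MCC) computed on pooled fold counts.

Metrics are pooled over folds — a single confusion table summed across all
held-out predictions — rather than averaged per fold, so one run yields one
SN/SP/ACC/MCC row per configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from exprules.feature_table import FeatureTable

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "MetricSet",
    "compute_metrics",
    "stratified_folds",
    "train_classifier",
    "cross_validate",
    "ALGORITHMS",
]

ALGORITHMS = ("random_forest", "ripper", "one_nn", "linear_svm", "logistic")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train and with what parameters.

    random_forest accepts ``B`` (trees, default 100) and ``m`` (features per
    split, default floor(log2(M)) + 1).  ripper accepts any RipperParams
    field.  The seed drives every stochastic component.
    """

    algorithm: str = "random_forest"
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.algorithm == "random_forest" and self.params.get("B", 1) < 1:
            raise ValueError("random_forest needs B >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    ACC: float
    MCC: float


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Zero denominators: SN/SP fall back to 0 with a warning, MCC to 0.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion table")
    if tp + fn == 0:
        warnings.warn("no positive samples: SN undefined, reported as 0", stacklevel=2)
        sn = 0.0
    else:
        sn = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples: SP undefined, reported as 0", stacklevel=2)
        sp = 0.0
    else:
        sp = tn / (tn + fp)
    acc = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(SN=sn, SP=sp, ACC=acc, MCC=mcc)


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds, deterministically.

    Fold sizes differ by at most one overall and within each class.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = fold
    return assignment


class _RipperAdapter:
    """sklearn-style wrapper around the rule learner for CV plumbing."""

    def __init__(self, feature_names: list[str], params: dict[str, Any], seed: int):
        self.feature_names = feature_names
        self.params = params
        self.seed = seed
        self.ruleset_ = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RipperAdapter":
        from exprules.ripper import RipperParams, ripper_train_arrays

        params = RipperParams(seed=self.seed, **self.params)
        self.ruleset_ = ripper_train_arrays(X, y, self.feature_names, params)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        from exprules.ripper import predict_arrays

        return predict_arrays(self.ruleset_, X, self.feature_names)


def train_classifier(table: FeatureTable, spec: ClassifierSpec):
    """Fit the classifier named by ``spec`` on the whole table.

    Returns an object with a ``predict(X) -> 0/1`` method.
    """
    if len(np.unique(table.labels)) < 2:
        raise ValueError("both classes must be present for training")
    model = _make_model(table.n_features, table.feature_names, spec)
    model.fit(table.values, table.labels)
    return model


def _make_model(n_features: int, feature_names: list[str], spec: ClassifierSpec):
    p = spec.params
    if spec.algorithm == "random_forest":
        b = int(p.get("B", 100))
        m = int(p.get("m", math.floor(math.log2(max(n_features, 2))) + 1))
        return RandomForestClassifier(
            n_estimators=b,
            max_features=min(m, n_features),
            bootstrap=True,
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "one_nn":
        return KNeighborsClassifier(n_neighbors=int(p.get("k", 1)))
    if spec.algorithm == "linear_svm":
        return LinearSVC(random_state=spec.seed)
    if spec.algorithm == "logistic":
        return LogisticRegression(max_iter=int(p.get("max_iter", 1000)), random_state=spec.seed)
    if spec.algorithm == "ripper":
        return _RipperAdapter(list(feature_names), dict(p), spec.seed)
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def cross_validate(
    table: FeatureTable,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> tuple[MetricSet, ConfusionCounts]:
    """k-fold CV with pooled confusion counts.

    ``folds`` may carry a precomputed assignment (e.g. to hold the partition
    fixed across feature-subset sizes); otherwise a stratified one is drawn
    from ``seed``.
    """
    if folds is None:
        folds = stratified_folds(table.labels, k, seed)
    folds = np.asarray(folds)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        model = _make_model(table.n_features, table.feature_names, spec)
        try:
            model.fit(table.values[train], table.labels[train])
            pred = model.predict(table.values[test])
        except Exception as exc:  # pragma: no cover - wrapped for context
            raise RuntimeError(f"classifier failed on fold {fold}: {exc}") from exc
        pooled = pooled + confusion_from_predictions(table.labels[test], pred)
    return compute_metrics(pooled), pooled
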
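"""Incremental feature selection over a ranked list and the
randomized-feature-subset significance test.

One IFS run holds the cross-validation partition fixed across all subset
sizes, so the curve varies only through the features used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from exprules.feature_table import FeatureTable, select_features
from exprules.model_eval import ClassifierSpec, MetricSet, cross_validate, stratified_folds
from exprules.mrmr import RankedFeatureList

__all__ = [
    "IFSCurve",
    "NullDistribution",
    "run_ifs",
    "optimal_point",
    "first_crossing",
    "random_subset_null",
    "sigma_excess",
    "null_boxplot_summary",
]


@dataclass(frozen=True)
class IFSCurve:
    """Ordered (subset_size, MetricSet) points for one classifier."""

    points: tuple[tuple[int, MetricSet], ...]
    classifier: ClassifierSpec

    def __post_init__(self) -> None:
        sizes = [i for i, _ in self.points]
        if sizes != sorted(set(sizes)):
            raise ValueError("subset sizes must be strictly increasing")

    def mccs(self) -> np.ndarray:
        return np.array([m.MCC for _, m in self.points])


@dataclass(frozen=True)
class NullDistribution:
    mccs: tuple[float, ...]
    mean: float
    sd: float
    anchor_feature: str
    subset_size: int
    seed: int


def run_ifs(
    table: FeatureTable,
    ranking: RankedFeatureList,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    max_size: int | None = None,
    stride: int = 1,
) -> IFSCurve:
    """Cross-validate nested prefixes of a ranked feature list.

    Evaluates subset sizes ``1, 1+stride, ...`` up to ``max_size`` (default
    all features).  The CV partition is drawn once and reused for every size.
    """
    if sorted(ranking.order) != list(range(table.n_features)):
        raise ValueError("ranking must be a permutation of the table's features")
    n = table.n_features
    max_size = n if max_size is None else max_size
    if not 1 <= max_size <= n:
        raise ValueError(f"max_size must be in [1, {n}]")
    folds = stratified_folds(table.labels, k, seed)
    sizes = list(range(1, max_size + 1, stride))
    if sizes[-1] != max_size:
        sizes.append(max_size)
    points = []
    for i in sizes:
        sub = select_features(table, ranking.order[:i])
        try:
            metrics, _ = cross_validate(sub, spec, k=k, seed=seed, folds=folds)
        except Exception as exc:
            raise RuntimeError(f"IFS failed at subset size {i}: {exc}") from exc
        points.append((i, metrics))
    return IFSCurve(points=tuple(points), classifier=spec)


def optimal_point(curve: IFSCurve) -> tuple[int, MetricSet]:
    """The curve point with maximal MCC; ties go to the smaller subset."""
    if not curve.points:
        raise ValueError("empty IFS curve")
    best = curve.points[0]
    for pt in curve.points[1:]:
        if pt[1].MCC > best[1].MCC + 1e-12:
            best = pt
    return best


def first_crossing(curve: IFSCurve, threshold: float) -> int | None:
    """Smallest subset size whose MCC reaches ``threshold``; None if never."""
    if not curve.points:
        raise ValueError("empty IFS curve")
    for i, m in curve.points:
        if m.MCC >= threshold:
            return i
    return None


def random_subset_null(
    table: FeatureTable,
    anchor: str,
    subset_size: int,
    spec: ClassifierSpec,
    n_iter: int = 1000,
    k: int = 10,
    seed: int = 0,
) -> NullDistribution:
    """MCC distribution over random feature subsets anchored on one feature.

    Each iterate evaluates ``{anchor} + (subset_size - 1)`` features sampled
    uniformly without replacement from the rest, under one fixed CV
    partition.  Reported sd is the sample (n - 1) standard deviation.
    """
    if anchor not in table.feature_names:
        raise ValueError(f"anchor feature {anchor!r} not in table")
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if subset_size > table.n_features:
        raise ValueError("subset_size exceeds the number of features")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    anchor_idx = table.feature_names.index(anchor)
    others = [j for j in range(table.n_features) if j != anchor_idx]
    rng = np.random.default_rng(seed)
    folds = stratified_folds(table.labels, k, seed)
    mccs = []
    for _ in range(n_iter):
        pick = rng.choice(len(others), size=subset_size - 1, replace=False)
        subset = sorted([anchor_idx] + [others[int(j)] for j in pick])
        sub = select_features(table, subset)
        metrics, _ = cross_validate(sub, spec, k=k, seed=seed, folds=folds)
        mccs.append(metrics.MCC)
    arr = np.array(mccs)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return NullDistribution(
        mccs=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        sd=sd,
        anchor_feature=anchor,
        subset_size=subset_size,
        seed=seed,
    )


def sigma_excess(observed_mcc: float, null: NullDistribution) -> float:
    """(observed - null mean) / null sd."""
    if null.sd <= 0:
        raise ValueError("null distribution has zero sd: sigma excess undefined")
    return (observed_mcc - null.mean) / null.sd


def null_boxplot_summary(null: NullDistribution) -> dict[str, float]:
    """Quartiles and 1.5*IQR whiskers of the stored MCC list."""
    arr = np.array(null.mccs)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return {
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
        "whisker_low": float(inside.min()) if inside.size else float(q1),
        "whisker_high": float(inside.max()) if inside.size else float(q3),
        "mean": null.mean,
        "sd": null.sd,
    }
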
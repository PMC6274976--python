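"""Mutual-information feature ranking: MaxRel and greedy mRMR (MID scheme).

Continuous features are discretized into three states at mean +/- alpha * sd
(population sd, alpha default 1) before any MI is computed; the class enters
as a 2-state variable.  The greedy mRMR step selects the feature maximizing

    I(f; class) - (1/|S|) * sum_{s in S} I(f; s)

over already-selected features S; ties break to the smaller original column
index.  A quotient (MIQ) variant is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from exprules.feature_table import FeatureTable

__all__ = [
    "DiscretizationSpec",
    "RankedFeatureList",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "maxrel_rank",
]


@dataclass(frozen=True)
class DiscretizationSpec:
    """Three-state binning thresholds at mean +/- alpha * sd."""

    alpha: float = 1.0
    n_states: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_states != 3:
            raise ValueError("only 3-state discretization is supported")


@dataclass(frozen=True)
class RankedFeatureList:
    """A permutation of feature indices with per-step scores.

    ``order[i]`` is the 0-based column index selected at step ``i``;
    ``scores[i]`` is the criterion value it was selected at.
    """

    order: tuple[int, ...]
    scores: tuple[float, ...]
    criterion: str
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of 0..N-1")
        if len(self.scores) != len(self.order):
            raise ValueError("scores and order must have equal length")
        if self.criterion not in ("mrmr", "maxrel"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def discretize(values, spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Map reals to states {-1, 0, +1} around mean +/- alpha * sd."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector with n >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mu = v.mean()
    sd = v.std()  # population sd
    out = np.zeros(v.size, dtype=np.int8)
    if sd > 0:
        out[v > mu + spec.alpha * sd] = 1
        out[v < mu - spec.alpha * sd] = -1
    return out


def mutual_information(x, y) -> float:
    """MI in bits between two discrete state vectors (0*log0 = 0)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n == 0:
        raise ValueError("empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


def _discretized_matrix(table: FeatureTable, spec: DiscretizationSpec) -> np.ndarray:
    states = np.empty(table.values.shape, dtype=np.int8)
    for j in range(table.n_features):
        states[:, j] = discretize(table.values[:, j], spec)
    return states


def _relevance(states: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return np.array(
        [mutual_information(states[:, j], labels) for j in range(states.shape[1])]
    )


def _check_table(table: FeatureTable) -> None:
    if table.n_features < 1:
        raise ValueError("table has no features to rank")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("both classes must be present to rank features")


def maxrel_rank(
    table: FeatureTable, spec: DiscretizationSpec = DiscretizationSpec()
) -> RankedFeatureList:
    """Sort features by descending MI with the class (ties: smaller index)."""
    _check_table(table)
    states = _discretized_matrix(table, spec)
    rel = _relevance(states, table.labels)
    order = np.lexsort((np.arange(rel.size), -rel))
    return RankedFeatureList(
        order=tuple(int(i) for i in order),
        scores=tuple(float(rel[i]) for i in order),
        criterion="maxrel",
        feature_names=tuple(table.feature_names[i] for i in order),
    )


def mrmr_rank(
    table: FeatureTable,
    spec: DiscretizationSpec = DiscretizationSpec(),
    scheme: str = "mid",
) -> RankedFeatureList:
    """Greedy mRMR ranking of all features.

    ``scheme`` selects the redundancy combination: "mid" (relevance minus
    mean redundancy, default) or "miq" (relevance over mean redundancy).
    """
    if scheme not in ("mid", "miq"):
        raise ValueError(f"unknown scheme {scheme!r}")
    _check_table(table)
    states = _discretized_matrix(table, spec)
    n_feat = states.shape[1]
    rel = _relevance(states, table.labels)

    # pairwise redundancy, computed lazily row by row as features are picked
    red = np.zeros((n_feat, n_feat))
    red_done = np.zeros(n_feat, dtype=bool)

    order: list[int] = []
    scores: list[float] = []
    remaining = set(range(n_feat))
    red_sum = np.zeros(n_feat)

    first = int(np.lexsort((np.arange(n_feat), -rel))[0])
    order.append(first)
    scores.append(float(rel[first]))
    remaining.discard(first)

    while remaining:
        last = order[-1]
        if not red_done[last]:
            for j in range(n_feat):
                red[last, j] = mutual_information(states[:, last], states[:, j])
            red_done[last] = True
        red_sum += red[last]
        k = len(order)
        best_j, best_score = -1, -np.inf
        for j in sorted(remaining):
            mean_red = red_sum[j] / k
            if scheme == "mid":
                score = rel[j] - mean_red
            else:
                score = rel[j] / max(mean_red, 1e-12)
            if score > best_score + 1e-15:
                best_j, best_score = j, score
        order.append(best_j)
        scores.append(float(best_score))
        remaining.discard(best_j)

    return RankedFeatureList(
        order=tuple(order),
        scores=tuple(scores),
        criterion="mrmr",
        feature_names=tuple(table.feature_names[i] for i in order),
    )
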
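"""Coverage-corrected entropy of a cross-facet CPM profile and the derived
expression-specificity score (1 - normalized entropy; higher = more exclusive).

The estimator applies the Chao-Shen coverage adjustment with a
Horvitz-Thompson correction: with ``n`` total counts and ``f1`` singletons,
sample coverage is ``C = 1 - f1/n`` (``C = 1 - (n-1)/n`` when every count is
a singleton, to avoid annihilating the estimator), adjusted proportions are
``p_i = C * c_i / n`` and

    H = - sum_i  p_i * log2(p_i) / (1 - (1 - p_i)**n)

over facets with positive counts.  All entropies are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpressionProfile",
    "EntropyResult",
    "chao_shen_entropy",
    "expression_specificity",
    "integerize_cpm",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """A named non-negative CPM vector over K >= 1 facets."""

    facet_names: tuple[str, ...]
    cpm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.facet_names) < 1 or len(self.facet_names) != len(self.cpm):
            raise ValueError("facet_names and cpm must be equal-length, K >= 1")
        arr = np.asarray(self.cpm, dtype=float)
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise ValueError("cpm values must be finite and non-negative")


@dataclass(frozen=True)
class EntropyResult:
    entropy_bits: float
    coverage: float
    n_pseudo_counts: int
    specificity: float


def chao_shen_entropy(counts) -> EntropyResult:
    """Coverage-adjusted Shannon entropy (bits) of a count vector.

    Parameters
    ----------
    counts:
        K non-negative integers, at least one positive.

    Returns
    -------
    EntropyResult
        Entropy in bits, the estimated coverage, the count total and the
        normalized specificity ``clamp(1 - H/log2(K), 0, 1)`` (1.0 for K=1).
    """
    c = np.asarray(counts)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if not np.all(np.isfinite(c.astype(float))):
        raise ValueError("counts must be finite")
    if np.any(c.astype(float) < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(c.astype(float), np.round(c.astype(float))):
        raise ValueError("counts must be integers (round CPM first)")
    c = np.round(c.astype(float)).astype(np.int64)
    n = int(c.sum())
    if n == 0:
        raise ValueError("all-zero profile: entropy undefined")

    f1 = int(np.sum(c == 1))
    coverage = 1.0 - (n - 1) / n if f1 == n else 1.0 - f1 / n

    pos = c[c > 0].astype(float)
    p = coverage * pos / n
    # Horvitz-Thompson inclusion weight; p>0 guaranteed since coverage>0.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = -p * np.log2(p) / (1.0 - np.power(1.0 - p, n))
    h = float(np.sum(terms))
    h = max(h, 0.0)

    k = c.size
    if k == 1:
        spec = 1.0
    else:
        spec = float(np.clip(1.0 - h / np.log2(k), 0.0, 1.0))
    return EntropyResult(entropy_bits=h, coverage=float(coverage), n_pseudo_counts=n, specificity=spec)


def integerize_cpm(cpm) -> np.ndarray:
    """Round a CPM vector to integer counts.

    If every value rounds to zero but some CPM is positive, the largest facet
    receives a single pseudo-count so the profile stays usable.
    """
    arr = np.asarray(cpm, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cpm must be finite")
    if arr.size and arr.min() < 0:
        raise ValueError("cpm must be non-negative")
    counts = np.round(arr).astype(np.int64)
    if counts.sum() == 0 and arr.size and arr.max() > 0:
        counts[int(np.argmax(arr))] = 1
    return counts


def expression_specificity(profile: ExpressionProfile | np.ndarray) -> float:
    """Specificity in [0, 1] of a CPM profile: 1 - H/log2(K), clamped.

    K = 1 profiles are maximally exclusive by definition (specificity 1.0).
    """
    cpm = profile.cpm if isinstance(profile, ExpressionProfile) else profile
    counts = integerize_cpm(np.asarray(cpm, dtype=float))
    if counts.sum() == 0:
        raise ValueError("profile has no expression: specificity undefined")
    return chao_shen_entropy(counts).specificity
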
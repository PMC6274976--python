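"""Synthetic labeled expression tables with known ground truth.

The generator emits zero-inflated log-normal CPM over a set of cell facets,
with the positive class (lncRNA) lower-expressed, more zero-inflated and
hence more facet-exclusive, plus the two derived columns every downstream
stage expects: the maximum CPM over facets and the expression specificity of
the facet profile (computed, not simulated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from exprules.feature_table import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    SPECIFICITY_FEATURE,
    FeatureTable,
)
from exprules.ripper import Rule, RuleSet, apply_ruleset, parse_ruleset
from exprules.specificity import expression_specificity

__all__ = ["SyntheticSpec", "generate_table", "table3_fixture", "REFERENCE_RULES_TEXT"]

MAX_CPM_FEATURE = "Max cpm in all facet"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the zero-inflated log-normal table generator.

    ``effect_log2`` is the mean log2-CPM excess of the negative class over
    the positive class on informative facets only.
    """

    n_pos: int = 500
    n_neg: int = 500
    n_facets: int = 69
    n_informative: int = 10
    effect_log2: float = 2.0
    dropout_pos: float = 0.6
    dropout_neg: float = 0.2
    sigma_log2: float = 1.0
    base_log2: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if not 0 < self.n_facets:
            raise ValueError("n_facets must be positive")
        if not 0 <= self.n_informative <= self.n_facets:
            raise ValueError("n_informative must be in [0, n_facets]")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        for d in (self.dropout_pos, self.dropout_neg):
            if not 0 <= d < 1:
                raise ValueError("dropout probabilities must be in [0, 1)")
        if self.sigma_log2 < 0:
            raise ValueError("sigma_log2 must be >= 0")


def generate_table(spec: SyntheticSpec) -> tuple[FeatureTable, list[int]]:
    """Draw a labeled table; returns it with the informative facet indices.

    Facet CPM is 0 with the class dropout probability, else
    ``2**(mu + sigma*z)`` with standard-normal z; the class mean differs by
    ``effect_log2`` on informative facets only.  Appended columns: max CPM
    over facets and the computed expression specificity, giving
    ``n_facets + 2`` features.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = np.r_[np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    informative = list(range(spec.n_informative))

    mu = np.full((2, spec.n_facets), spec.base_log2)
    mu[1, informative] -= spec.effect_log2  # positives sit below negatives
    dropout = np.where(labels == 1, spec.dropout_pos, spec.dropout_neg)

    z = rng.standard_normal((n, spec.n_facets))
    cpm = np.power(2.0, mu[labels] + spec.sigma_log2 * z)
    keep = rng.random((n, spec.n_facets)) >= dropout[:, None]
    cpm = np.where(keep, cpm, 0.0)

    # guarantee at least one expressed facet per sample (specificity needs it)
    dead = ~keep.any(axis=1)
    if dead.any():
        j = rng.integers(0, spec.n_facets, size=int(dead.sum()))
        rows = np.flatnonzero(dead)
        cpm[rows, j] = np.power(
            2.0, mu[labels[rows], j] + spec.sigma_log2 * rng.standard_normal(rows.size)
        )

    max_cpm = cpm.max(axis=1)
    specificity = np.array([expression_specificity(row) for row in cpm])

    facet_names = [f"Facet {i + 1:02d}" for i in range(spec.n_facets)]
    feature_names = facet_names + [MAX_CPM_FEATURE, SPECIFICITY_FEATURE]
    values = np.column_stack([cpm, max_cpm, specificity])
    sample_ids = [
        f"{POSITIVE_LABEL if y else NEGATIVE_LABEL}_{i:05d}" for i, y in enumerate(labels)
    ]
    table = FeatureTable(sample_ids, labels, feature_names, values)
    return table, informative


# --------------------------------------------------------------------------
# reference ruleset fixture
# --------------------------------------------------------------------------

#: Hand-transcribed published 18-rule model over the top-10 ranked features:
#: 17 conjunctive lncRNA rules plus a terminal mRNA default.
REFERENCE_RULES_TEXT = """\
(Neuronal stem cell <= 2.58) and (Mesenchymal cell <= 1.44) and (Intestinal epithelial cell <= 0) and (Mesenchymal cell <= 0.197) and (Expression specificity >= 0.552495) => lncRNA
(Neuronal stem cell <= 2.58) and (Hepatocyte <= 0) and (Mast cell <= 0.151) => lncRNA
(Neuronal stem cell <= 2.58) and (Hepatocyte <= 0) and (Intestinal epithelial cell <= 0.246) and (Mesenchymal cell <= 2.04) and (Neuronal stem cell <= 0) => lncRNA
(Neuronal stem cell <= 5.17) and (Mast cell <= 0.842) and (Intestinal epithelial cell <= 0.737) and (Neuronal stem cell <= 0.542) and (Mesenchymal cell <= 2.75) => lncRNA
(Neuronal stem cell <= 2.58) and (Hepatocyte <= 1.73) and (Intestinal epithelial cell <= 0.246) and (Mesenchymal cell <= 2.63) and (Neuronal stem cell <= 0) => lncRNA
(Neuronal stem cell <= 2.58) and (Hepatocyte <= 1.73) and (Mast cell <= 0.352) and (Expression specificity <= 0.299388) and (Mast cell <= 0) => lncRNA
(Neuronal stem cell <= 5.17) and (Hepatocyte <= 1.73) and (Intestinal epithelial cell <= 0.246) and (Expression specificity >= 0.497214) and (Lymphocyte of b lineage >= 1.23) => lncRNA
(Neuronal stem cell <= 2.58) and (Hepatocyte <= 1.73) and (Mesenchymal cell <= 1.44) and (Intestinal epithelial cell <= 0) => lncRNA
(Neuronal stem cell <= 5.17) and (Mesenchymal cell <= 4.52) and (Reticulocyte <= 0) and (Fibroblast of the conjuctiva <= 0) and (Hepatocyte <= 3.46) and (Expression specificity >= 0.311106) and (Intestinal epithelial cell <= 4.18) and (Neuronal stem cell <= 2.71) => lncRNA
(Neuronal stem cell <= 5.17) and (Mast cell <= 0.842) and (Intestinal epithelial cell <= 1.72) and (Hepatocyte <= 0) and (Fibroblast of the conjuctiva <= 0) => lncRNA
(Neuronal stem cell <= 5.17) and (Hepatocyte <= 5.19) and (Intestinal epithelial cell <= 1.23) and (Neuronal stem cell <= 0.542) and (Mesenchymal cell <= 10.1) and (Mast cell <= 0.907) => lncRNA
(Neuronal stem cell <= 2.58) and (Mesenchymal cell <= 4.5) and (Intestinal epithelial cell <= 0.983) and (Hepatocyte <= 0) and (Fibroblast of the conjuctiva <= 0) => lncRNA
(Neuronal stem cell <= 5.17) and (Mesenchymal cell <= 5.18) and (Mesenchymal cell <= 1.45) and (Neutrophil >= 0.848) and (Expression specificity <= 0.333673) and (Mesenchymal cell <= 0.904) and (Fibroblast of the conjuctiva <= 0) => lncRNA
(Neuronal stem cell <= 5.17) and (Mesenchymal cell <= 5.18) and (Neuronal stem cell <= 2.58) and (Intestinal epithelial cell <= 0.737) and (Neuronal stem cell <= 0) and (Expression specificity <= 0.517863) and (Mesenchymal cell >= 2.87) => lncRNA
(Neuronal stem cell <= 5.17) and (Mast cell <= 1.06) and (Hepatocyte <= 5.19) and (Neuronal stem cell <= 0.542) and (Intestinal epithelial cell <= 6.88) and (Mesenchymal cell <= 28.5) => lncRNA
(Neuronal stem cell <= 5.17) and (Mesenchymal cell <= 5.28) and (Fibroblast of the conjuctiva <= 0) and (Mast cell <= 0.842) and (Intestinal epithelial cell <= 11.8) and (Neuronal stem cell <= 2.58) and (Hepatocyte <= 20.1) => lncRNA
(Neuronal stem cell <= 7.75) and (Intestinal epithelial cell <= 1.72) and (Mesenchymal cell <= 4.52) and (Neuronal stem cell <= 2.58) and (Lymphocyte of b lineage <= 4.07) and (Neutrophil >= 5.72) and (Mast cell <= 19) and (Expression specificity >= 0.115115) => lncRNA
Otherwise => mRNA
"""

#: Feature names appearing in the reference top-13 ranked list.
REFERENCE_TOP13_FEATURES = [
    SPECIFICITY_FEATURE,
    "Intestinal epithelial cell",
    "Neutrophil",
    "Hepatocyte",
    "Mast cell",
    "Fibroblast of the conjuctiva",
    "Reticulocyte",
    "Mesenchymal cell",
    "Lymphocyte of b lineage",
    "Neuronal stem cell",
    "Macrophage",
    "Pericyte cell",
    MAX_CPM_FEATURE,
]

_HIGH = 1000.0  # expression value no reference rule's <= condition admits


def _box_for_rule(rule: Rule, features: list[str]) -> dict[str, tuple[float, float]]:
    box: dict[str, tuple[float, float]] = {}
    for name in features:
        hi_default = 1.0 if name == SPECIFICITY_FEATURE else _HIGH
        box[name] = (0.0, hi_default)
    for c in rule.conditions:
        lo, hi = box[c.feature_name]
        if c.relation == "<=":
            hi = min(hi, c.threshold)
        else:
            lo = max(lo, c.threshold)
        if lo > hi:
            raise ValueError(f"infeasible rule conditions on {c.feature_name!r}")
        box[c.feature_name] = (lo, hi)
    return box


def _sample_for_rule(
    ruleset: RuleSet, target_index: int, features: list[str]
) -> dict[str, float]:
    """Construct a sample firing exactly rule ``target_index`` (1-based).

    Starts from the loosest point inside the target rule's feasible box
    (high expression everywhere unconstrained, zero specificity) and then
    perturbs free features to break any earlier rule that also fires.
    """
    n_rules = len(ruleset.rules)
    if target_index == n_rules + 1:  # the default rule
        sample = {name: _HIGH for name in features}
        sample[SPECIFICITY_FEATURE] = 0.0
        return sample
    rule = ruleset.rules[target_index - 1]
    box = _box_for_rule(rule, features)
    constrained = {c.feature_name for c in rule.conditions}
    sample: dict[str, float] = {}
    for name in features:
        lo, hi = box[name]
        if name not in constrained:
            sample[name] = 0.0 if name == SPECIFICITY_FEATURE else _HIGH
        else:
            has_ge = any(
                c.feature_name == name and c.relation == ">=" for c in rule.conditions
            )
            has_le = any(
                c.feature_name == name and c.relation == "<=" for c in rule.conditions
            )
            sample[name] = lo if (has_ge and not has_le) else hi

    for _ in range(4 * n_rules):  # repair loop; each pass breaks one earlier rule
        fired = next(
            (i for i, r in enumerate(ruleset.rules[: target_index - 1], start=1) if r.matches(sample)),
            None,
        )
        if fired is None:
            break
        earlier = ruleset.rules[fired - 1]
        for c in earlier.conditions:
            lo, hi = box[c.feature_name]
            if c.relation == "<=" and hi > c.threshold:
                sample[c.feature_name] = hi  # move above the earlier cap
                break
            if c.relation == ">=" and lo < c.threshold:
                nudge = min(hi, np.nextafter(c.threshold, -np.inf))
                if lo <= nudge < c.threshold:
                    sample[c.feature_name] = nudge
                    break
        else:
            raise ValueError(
                f"cannot construct a sample firing rule {target_index}: "
                f"rule {fired} always fires first"
            )
    outcome, fired_index = apply_ruleset(ruleset, sample)
    if fired_index != target_index:
        raise ValueError(
            f"sample construction for rule {target_index} landed on rule {fired_index}"
        )
    return sample


def table3_fixture() -> tuple[RuleSet, FeatureTable, list[int]]:
    """The transcribed 18-rule reference model plus an engineered table.

    Returns ``(ruleset, table, expected_fired)`` where row ``i`` of the
    table fires rule ``expected_fired[i]`` (1-based; the default rule is
    index 18).
    """
    ruleset = parse_ruleset(REFERENCE_RULES_TEXT)
    features = list(REFERENCE_TOP13_FEATURES)
    rows = []
    expected: list[int] = []
    n_total = len(ruleset.rules) + 1
    for idx in range(1, n_total + 1):
        try:
            sample = _sample_for_rule(ruleset, idx, features)
        except ValueError:
            continue  # a rule shadowed by earlier ones has no firing sample
        rows.append([sample[name] for name in features])
        expected.append(idx)
    outcomes = [
        ruleset.rules[i - 1].outcome if i <= len(ruleset.rules) else ruleset.default_class
        for i in expected
    ]
    labels = np.array([int(o == POSITIVE_LABEL) for o in outcomes])
    table = FeatureTable(
        sample_ids=[f"rule_{i:02d}_probe" for i in expected],
        labels=labels,
        feature_names=features,
        values=np.array(rows, dtype=float),
    )
    return ruleset, table, expected
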
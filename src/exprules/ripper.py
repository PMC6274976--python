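"""From-scratch RIPPER rule induction for binary numeric tables.

The learner targets the minority class: rules are grown greedily by FOIL
information gain on a grow partition, pruned on a held-out prune partition
by the (p - n)/(p + n) criterion, and the rule-adding loop stops when a
candidate's prune-set error exceeds 1/2 or the ruleset description length
exceeds the minimum seen plus a slack.  Optimization passes let each rule
compete against a freshly grown replacement and a grown-out revision, with
the description-length-minimizing variant kept; rules whose removal lowers
the total description length are finally deleted.

Rule application is first-match over an ordered list with a terminal default
class ("Otherwise").  Fired-rule indices are reported 1-based, the default
rule being ``len(rules) + 1``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from exprules.feature_table import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    FeatureTable,
)

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "RipperParams",
    "ripper_train",
    "ripper_train_arrays",
    "apply_ruleset",
    "predict_arrays",
    "parse_ruleset",
    "format_ruleset",
    "ruleset_description_length",
]

LE = "<="
GE = ">="


@dataclass(frozen=True)
class Condition:
    feature_name: str
    relation: str  # "<=" or ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.relation not in (LE, GE):
            raise ValueError(f"relation must be {LE!r} or {GE!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.relation == LE else value >= self.threshold


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    outcome: str

    def matches(self, sample: dict) -> bool:
        for c in self.conditions:
            if c.feature_name not in sample:
                raise KeyError(f"sample lacks feature {c.feature_name!r}")
            if not c.holds(sample[c.feature_name]):
                return False
        return True


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]
    default_class: str

    def feature_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            for c in r.conditions:
                if c.feature_name not in seen:
                    seen.append(c.feature_name)
        return seen


@dataclass(frozen=True)
class RipperParams:
    prune_fraction: float = 1.0 / 3.0
    min_covered: int = 2
    optimization_passes: int = 2
    dl_slack_bits: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prune_fraction < 1.0:
            raise ValueError("prune_fraction must be in (0, 1)")
        if self.min_covered < 1:
            raise ValueError("min_covered must be positive")
        if self.optimization_passes < 0:
            raise ValueError("optimization_passes must be non-negative")
        if self.dl_slack_bits <= 0:
            raise ValueError("dl_slack_bits must be positive")


# --------------------------------------------------------------------------
# rule application
# --------------------------------------------------------------------------

def apply_ruleset(ruleset: RuleSet, sample: dict) -> tuple[str, int]:
    """First-match rule application.

    Returns ``(class, fired_index)`` with 1-based indices; the default rule
    has index ``len(rules) + 1``.
    """
    for i, rule in enumerate(ruleset.rules, start=1):
        if rule.matches(sample):
            return rule.outcome, i
    return ruleset.default_class, len(ruleset.rules) + 1


def _rule_mask(rule: Rule, X: np.ndarray, col: dict[str, int]) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for c in rule.conditions:
        if c.feature_name not in col:
            raise KeyError(f"table lacks feature {c.feature_name!r}")
        v = X[:, col[c.feature_name]]
        mask &= (v <= c.threshold) if c.relation == LE else (v >= c.threshold)
    return mask


def predict_arrays(ruleset: RuleSet, X: np.ndarray, feature_names: list[str]) -> np.ndarray:
    """Vectorized first-match prediction; returns 0/1 (1 = positive class)."""
    col = {n: j for j, n in enumerate(feature_names)}
    out = np.full(X.shape[0], ruleset.default_class == POSITIVE_LABEL, dtype=int)
    undecided = np.ones(X.shape[0], dtype=bool)
    for rule in ruleset.rules:
        fires = undecided & _rule_mask(rule, X, col)
        out[fires] = int(rule.outcome == POSITIVE_LABEL)
        undecided &= ~fires
        if not undecided.any():
            break
    return out


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_COND_RE = re.compile(r"\(\s*(.+?)\s*(<=|>=|≤|≥)\s*([-+0-9.eE]+)\s*\)")
_REL_MAP = {"≤": LE, "≥": GE, LE: LE, GE: GE}


def format_ruleset(ruleset: RuleSet) -> str:
    """Render a ruleset as text, one rule per line, terminal Otherwise line."""
    lines = []
    for rule in ruleset.rules:
        conds = " and ".join(
            f"({c.feature_name} {c.relation} {_fmt_num(c.threshold)})" for c in rule.conditions
        )
        lines.append(f"{conds} => {rule.outcome}")
    lines.append(f"Otherwise => {ruleset.default_class}")
    return "\n".join(lines) + "\n"


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def parse_ruleset(text: str) -> RuleSet:
    """Inverse of :func:`format_ruleset`; accepts unicode or ASCII relations."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty rule text")
    rules: list[Rule] = []
    default_class: str | None = None
    for ln in lines:
        if default_class is not None:
            raise ValueError("rules after the Otherwise line")
        if "=>" not in ln:
            raise ValueError(f"missing '=>' in rule line: {ln!r}")
        lhs, _, outcome = ln.rpartition("=>")
        lhs, outcome = lhs.strip(), outcome.strip()
        if not outcome:
            raise ValueError(f"missing outcome in rule line: {ln!r}")
        if lhs.lower() == "otherwise":
            default_class = outcome
            continue
        conds = []
        matched_spans = []
        for m in _COND_RE.finditer(lhs):
            conds.append(
                Condition(m.group(1), _REL_MAP[m.group(2)], float(m.group(3)))
            )
            matched_spans.append(m.span())
        if not conds:
            raise ValueError(f"no parsable conditions in rule line: {ln!r}")
        residue = lhs
        for a, b in reversed(matched_spans):
            residue = residue[:a] + residue[b:]
        if residue.replace("and", "").strip():
            raise ValueError(f"malformed condition text in rule line: {ln!r}")
        rules.append(Rule(tuple(conds), outcome))
    if default_class is None:
        raise ValueError("missing terminal 'Otherwise => <class>' line")
    return RuleSet(tuple(rules), default_class)


# --------------------------------------------------------------------------
# description length (MDL) accounting
# --------------------------------------------------------------------------

def _log2_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / math.log(2))


def _theory_bits(n_conditions: int, n_candidates: int) -> float:
    # 0.5x redundancy adjustment after Cohen (1995); a rule costs the bits
    # to announce its length plus to pick each condition from the pool.
    k = n_conditions
    return 0.5 * (math.log2(k + 1) + k * math.log2(max(n_candidates, 2)))


def _data_bits(t: int, covered: int, fp: int, fn: int) -> float:
    # exceptions coding: identify the fp errors among covered examples and
    # the fn errors among the rest
    uncovered = t - covered
    return (
        math.log2(covered + 1)
        + _log2_choose(covered, fp)
        + math.log2(uncovered + 1)
        + _log2_choose(uncovered, fn)
    )


def ruleset_description_length(
    rules: list[tuple[tuple[int, str, float], ...]],
    X: np.ndarray,
    t: np.ndarray,
    n_candidates: int,
) -> float:
    """Total DL in bits: theory bits per rule plus exception-coding bits.

    ``rules`` use internal (column, relation, threshold) conditions; ``t`` is
    the boolean target-class vector.
    """
    covered = np.zeros(X.shape[0], dtype=bool)
    theory = 0.0
    for conds in rules:
        theory += _theory_bits(len(conds), n_candidates)
        covered |= _conds_mask(conds, X)
    fp = int(np.sum(covered & ~t))
    fn = int(np.sum(~covered & t))
    return theory + _data_bits(X.shape[0], int(covered.sum()), fp, fn)


# --------------------------------------------------------------------------
# training internals (internal rules are tuples of (col, rel, threshold))
# --------------------------------------------------------------------------

def _conds_mask(conds, X: np.ndarray) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for j, rel, thr in conds:
        v = X[:, j]
        mask &= (v <= thr) if rel == LE else (v >= thr)
    return mask


def _best_condition(X: np.ndarray, t: np.ndarray, covered: np.ndarray):
    """Best single numeric condition by FOIL gain over the covered subset.

    Returns ``(gain, (col, rel, threshold))`` or ``None`` when no condition
    has positive gain.  Ties break to smaller column, then "<=", then the
    smaller threshold.
    """
    idx = np.flatnonzero(covered)
    if idx.size == 0:
        return None
    tc = t[idx]
    p0 = int(tc.sum())
    n0 = idx.size - p0
    if p0 == 0:
        return None
    base = math.log2(p0 / (p0 + n0))
    best = None
    best_gain = 1e-9  # require strictly positive gain
    for j in range(X.shape[1]):
        v = X[idx, j]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ts = tc[order]
        cum_p = np.cumsum(ts)
        # rightmost occurrence of each distinct value -> threshold candidates
        last = np.flatnonzero(np.r_[vs[1:] != vs[:-1], True])
        # v <= threshold
        p_le = cum_p[last].astype(float)
        c_le = (last + 1).astype(float)
        n_le = c_le - p_le
        with np.errstate(divide="ignore", invalid="ignore"):
            gain_le = p_le * (np.log2(np.where(p_le > 0, p_le / (p_le + n_le), 1.0)) - base)
        # v >= threshold (thresholds are leftmost occurrences = last[i-1]+1)
        p_tot, c_tot = float(p0), float(idx.size)
        first = np.r_[0, last[:-1] + 1]
        p_ge = p_tot - np.r_[0.0, p_le[:-1]]
        c_ge = c_tot - np.r_[0.0, c_le[:-1]]
        n_ge = c_ge - p_ge
        with np.errstate(divide="ignore", invalid="ignore"):
            gain_ge = p_ge * (np.log2(np.where(p_ge > 0, p_ge / (p_ge + n_ge), 1.0)) - base)
        for rel, gains, pos_at in ((LE, gain_le, last), (GE, gain_ge, first)):
            k = int(np.argmax(gains))
            g = float(gains[k])
            if g > best_gain + 1e-12:
                # skip the degenerate all-covering condition (no refinement)
                cov = c_le[k] if rel == LE else c_ge[k]
                if cov == idx.size:
                    alt = _second_best(gains, k)
                    if alt is None:
                        continue
                    k, g = alt
                    if g <= best_gain + 1e-12:
                        continue
                thr = float(vs[last[k]] if rel == LE else vs[first[k]])
                best_gain = g
                best = (j, rel, thr)
    if best is None:
        return None
    return best_gain, best


def _second_best(gains: np.ndarray, skip: int):
    if gains.size <= 1:
        return None
    g = gains.copy()
    g[skip] = -np.inf
    k = int(np.argmax(g))
    if not np.isfinite(g[k]):
        return None
    return k, float(g[k])


def _grow_rule(
    X: np.ndarray, t: np.ndarray, start: tuple = ()
) -> tuple[tuple[int, str, float], ...]:
    """Greedily append conditions until no negatives are covered or no
    condition has positive FOIL gain."""
    conds = list(start)
    covered = _conds_mask(conds, X)
    while True:
        if not np.any(t[covered] == False):  # noqa: E712 - vectorized bool
            break
        if not covered.any() or not t[covered].any():
            break
        found = _best_condition(X, t, covered)
        if found is None:
            break
        _, cond = found
        new_covered = covered & _conds_mask([cond], X)
        if new_covered.sum() == covered.sum():
            break
        conds.append(cond)
        covered = new_covered
    return tuple(conds)


def _prune_rule(conds, X: np.ndarray, t: np.ndarray, keep_at_least: int = 1):
    """Delete a final sequence of conditions maximizing (p - n)/(p + n) on
    the prune data; ties keep the longer rule."""
    if not conds:
        return conds
    best_i, best_v = len(conds), _rule_value(conds, X, t)
    for i in range(len(conds) - 1, keep_at_least - 1, -1):
        v = _rule_value(conds[:i], X, t)
        if v > best_v + 1e-12:
            best_i, best_v = i, v
    return tuple(conds[:best_i])


def _rule_value(conds, X: np.ndarray, t: np.ndarray) -> float:
    mask = _conds_mask(conds, X)
    p = int(t[mask].sum())
    n = int(mask.sum()) - p
    if p + n == 0:
        return -1.0
    return (p - n) / (p + n)


def _split_grow_prune(n: int, prune_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_prune = max(1, int(round(n * prune_fraction))) if n > 3 else max(1, n // 3)
    prune_idx = perm[:n_prune]
    grow_idx = perm[n_prune:]
    if grow_idx.size == 0:
        grow_idx, prune_idx = prune_idx, grow_idx
    return grow_idx, prune_idx


def _count_candidates(X: np.ndarray) -> int:
    return int(sum(2 * np.unique(X[:, j]).size for j in range(X.shape[1])))


def _grow_and_prune(
    X: np.ndarray,
    t: np.ndarray,
    params: RipperParams,
    rng: np.random.Generator,
    start: tuple = (),
):
    """One grow/prune cycle on a fresh random partition of (X, t).

    Returns ``(conds, prune_error)`` where prune_error is the covered-set
    error rate on the prune partition (0 when nothing is covered there).
    """
    grow_idx, prune_idx = _split_grow_prune(X.shape[0], params.prune_fraction, rng)
    if not t[grow_idx].any():  # no positives to grow from
        return None
    conds = _grow_rule(X[grow_idx], t[grow_idx], start=start)
    if not conds:
        return None
    if prune_idx.size:
        conds = _prune_rule(conds, X[prune_idx], t[prune_idx])
        mask = _conds_mask(conds, X[prune_idx])
        p = int(t[prune_idx][mask].sum())
        n = int(mask.sum()) - p
        err = n / (p + n) if (p + n) > 0 else 0.0
    else:
        err = 0.0
    return conds, err


def ripper_train_arrays(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    params: RipperParams = RipperParams(),
) -> RuleSet:
    """Train on raw arrays; ``y`` is 0/1 with 1 = positive (lncRNA)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to learn rules")

    # rules target the minority class; ties go to the positive class
    target = 1 if counts[classes == 1] <= counts[classes == 0] else 0
    target_label = POSITIVE_LABEL if target == 1 else NEGATIVE_LABEL
    default_label = NEGATIVE_LABEL if target == 1 else POSITIVE_LABEL

    t_all = y == target
    rng = np.random.default_rng(params.seed)
    n_candidates = _count_candidates(X)

    rules: list[tuple] = []
    remaining = np.ones(X.shape[0], dtype=bool)
    min_dl = ruleset_description_length([], X, t_all, n_candidates)

    while t_all[remaining].any():
        sub = np.flatnonzero(remaining)
        got = _grow_and_prune(X[sub], t_all[sub], params, rng)
        if got is None:
            break
        conds, prune_err = got
        if prune_err > 0.5:
            break
        full_mask = _conds_mask(conds, X[sub])
        if int(full_mask.sum()) < params.min_covered or not t_all[sub][full_mask].any():
            break
        rules.append(conds)
        dl = ruleset_description_length(rules, X, t_all, n_candidates)
        if dl > min_dl + params.dl_slack_bits:
            rules.pop()
            break
        min_dl = min(min_dl, dl)
        remaining[sub[full_mask]] = False

    rules = _optimize(rules, X, t_all, params, rng, n_candidates)
    rules = _delete_bad_rules(rules, X, t_all, n_candidates)

    out_rules = tuple(
        Rule(
            tuple(Condition(feature_names[j], rel, thr) for j, rel, thr in conds),
            target_label,
        )
        for conds in rules
    )
    return RuleSet(out_rules, default_label)


def _optimize(rules, X, t_all, params: RipperParams, rng, n_candidates):
    """Rule-by-rule competition: original vs fresh replacement vs revision,
    judged by total ruleset description length."""
    for _ in range(params.optimization_passes):
        for i in range(len(rules)):
            others = rules[:i] + rules[i + 1 :]
            covered_by_others = np.zeros(X.shape[0], dtype=bool)
            for conds in others:
                covered_by_others |= _conds_mask(conds, X)
            sub = np.flatnonzero(~covered_by_others)
            variants = [rules[i]]
            if sub.size >= 2 and t_all[sub].any():
                repl = _grow_and_prune(X[sub], t_all[sub], params, rng)
                if repl is not None:
                    variants.append(repl[0])
                revis = _grow_and_prune(X[sub], t_all[sub], params, rng, start=rules[i])
                if revis is not None:
                    variants.append(revis[0])
            dls = [
                ruleset_description_length(rules[:i] + [v] + rules[i + 1 :], X, t_all, n_candidates)
                for v in variants
            ]
            rules = rules[:i] + [variants[int(np.argmin(dls))]] + rules[i + 1 :]
    return rules


def _delete_bad_rules(rules, X, t_all, n_candidates):
    """Drop rules (scanning from the last) whose removal lowers total DL."""
    changed = True
    while changed and rules:
        changed = False
        dl = ruleset_description_length(rules, X, t_all, n_candidates)
        for i in range(len(rules) - 1, -1, -1):
            without = rules[:i] + rules[i + 1 :]
            if ruleset_description_length(without, X, t_all, n_candidates) < dl:
                rules = without
                changed = True
                break
    return rules


def ripper_train(table: FeatureTable, params: RipperParams = RipperParams()) -> RuleSet:
    """Learn an ordered ruleset from a labeled feature table."""
    return ripper_train_arrays(table.values, table.labels, table.feature_names, params)
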
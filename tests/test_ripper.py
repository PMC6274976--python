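import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exprules.feature_table import NEGATIVE_LABEL, POSITIVE_LABEL
from exprules.ripper import (
    Condition,
    RipperParams,
    Rule,
    RuleSet,
    apply_ruleset,
    format_ruleset,
    parse_ruleset,
    predict_arrays,
    ripper_train,
    ruleset_description_length,
)
from exprules.synthetic import REFERENCE_RULES_TEXT

from conftest import make_table


# ---------------------------------------------------------------------------
# rule model and application
# ---------------------------------------------------------------------------

def test_condition_validation():
    with pytest.raises(ValueError):
        Condition("x", "<", 1.0)
    with pytest.raises(ValueError):
        Condition("x", "<=", float("nan"))


def test_apply_first_match_and_default():
    rs = RuleSet(
        rules=(
            Rule((Condition("x", "<=", 1.0),), POSITIVE_LABEL),
            Rule((Condition("x", "<=", 5.0),), NEGATIVE_LABEL),
        ),
        default_class=POSITIVE_LABEL,
    )
    assert apply_ruleset(rs, {"x": 0.5}) == (POSITIVE_LABEL, 1)
    assert apply_ruleset(rs, {"x": 3.0}) == (NEGATIVE_LABEL, 2)
    assert apply_ruleset(rs, {"x": 9.0}) == (POSITIVE_LABEL, 3)


def test_apply_missing_feature():
    rs = RuleSet((Rule((Condition("x", "<=", 1.0),), POSITIVE_LABEL),), NEGATIVE_LABEL)
    with pytest.raises(KeyError):
        apply_ruleset(rs, {"y": 1.0})


def test_empty_ruleset_default():
    rs = RuleSet((), POSITIVE_LABEL)
    assert apply_ruleset(rs, {"anything": 42.0}) == (POSITIVE_LABEL, 1)


def test_rule_order_sensitivity():
    # overlapping rules with conflicting outcomes: order changes predictions
    r1 = Rule((Condition("x", "<=", 5.0),), POSITIVE_LABEL)
    r2 = Rule((Condition("x", ">=", 1.0),), NEGATIVE_LABEL)
    a = RuleSet((r1, r2), NEGATIVE_LABEL)
    b = RuleSet((r2, r1), NEGATIVE_LABEL)
    sample = {"x": 3.0}
    assert apply_ruleset(a, sample)[0] != apply_ruleset(b, sample)[0]


def test_predict_arrays_matches_apply():
    rs = parse_ruleset(REFERENCE_RULES_TEXT)
    names = rs.feature_names()
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 10, (50, len(names)))
    spec_col = names.index("Expression specificity")
    X[:, spec_col] = rng.uniform(0, 1, 50)
    preds = predict_arrays(rs, X, names)
    for i in range(50):
        outcome, _ = apply_ruleset(rs, dict(zip(names, X[i])))
        assert preds[i] == int(outcome == POSITIVE_LABEL)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_reference_rules_parse():
    rs = parse_ruleset(REFERENCE_RULES_TEXT)
    assert len(rs.rules) == 17
    assert rs.default_class == NEGATIVE_LABEL
    assert all(r.outcome == POSITIVE_LABEL for r in rs.rules)
    assert rs.rules[1].conditions == (
        Condition("Neuronal stem cell", "<=", 2.58),
        Condition("Hepatocyte", "<=", 0.0),
        Condition("Mast cell", "<=", 0.151),
    )


def test_roundtrip_reference():
    rs = parse_ruleset(REFERENCE_RULES_TEXT)
    assert parse_ruleset(format_ruleset(rs)) == rs


def test_parse_accepts_unicode_relations():
    rs = parse_ruleset("(Mast cell ≤ 0.151) and (Neutrophil ≥ 2) => lncRNA\nOtherwise => mRNA\n")
    assert rs.rules[0].conditions[0].relation == "<="
    assert rs.rules[0].conditions[1].relation == ">="


def test_parse_requires_otherwise():
    with pytest.raises(ValueError, match="Otherwise"):
        parse_ruleset("(x <= 1) => lncRNA\n")


def test_parse_rejects_malformed():
    with pytest.raises(ValueError):
        parse_ruleset("(x ?? 1) => lncRNA\nOtherwise => mRNA\n")
    with pytest.raises(ValueError):
        parse_ruleset("Otherwise => mRNA\n(x <= 1) => lncRNA\n")
    with pytest.raises(ValueError):
        parse_ruleset("")


@st.composite
def rulesets(draw):
    names = ["Facet A", "Facet B", "Specificity"]
    n_rules = draw(st.integers(0, 5))
    rules = []
    for _ in range(n_rules):
        n_conds = draw(st.integers(1, 4))
        conds = tuple(
            Condition(
                draw(st.sampled_from(names)),
                draw(st.sampled_from(["<=", ">="])),
                float(draw(st.decimals(min_value=-100, max_value=100, places=4))),
            )
            for _ in range(n_conds)
        )
        rules.append(Rule(conds, draw(st.sampled_from([POSITIVE_LABEL, NEGATIVE_LABEL]))))
    default = draw(st.sampled_from([POSITIVE_LABEL, NEGATIVE_LABEL]))
    return RuleSet(tuple(rules), default)


@given(rulesets())
@settings(max_examples=100, deadline=None)
def test_roundtrip_random_rulesets(rs):
    assert parse_ruleset(format_ruleset(rs)) == rs


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_clean_threshold_single_rule():
    rng = np.random.default_rng(12)
    x = rng.uniform(0, 1, 200)
    y = (x <= 0.4).astype(int)  # positives are the minority
    t = make_table(x, y, ["x"])
    rs = ripper_train(t, RipperParams(seed=0))
    assert len(rs.rules) == 1
    (rule,) = rs.rules
    assert rule.outcome == POSITIVE_LABEL and rs.default_class == NEGATIVE_LABEL
    # zero training errors
    pred = predict_arrays(rs, t.values, t.feature_names)
    np.testing.assert_array_equal(pred, y)
    # threshold bracketed by the class gap
    lo = x[y == 1].max()
    hi = x[y == 0].min()
    (cond,) = [c for c in rule.conditions if True][:1]
    assert cond.relation == "<="
    assert lo <= cond.threshold < hi


def test_pure_noise_no_rules():
    rng = np.random.default_rng(8)
    n = 500
    t = make_table(rng.uniform(0, 1, (n, 5)), rng.integers(0, 2, n))
    rs = ripper_train(t, RipperParams(seed=0))
    assert len(rs.rules) == 0


def test_training_deterministic(small_signal_table):
    table, _ = small_signal_table
    a = ripper_train(table, RipperParams(seed=5))
    b = ripper_train(table, RipperParams(seed=5))
    assert a == b


def test_minority_class_is_rule_target():
    rng = np.random.default_rng(2)
    n_pos, n_neg = 60, 140
    x = np.r_[rng.uniform(0, 0.4, n_pos), rng.uniform(0.6, 1.0, n_neg)]
    y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    t = make_table(x, y, ["x"])
    rs = ripper_train(t, RipperParams(seed=0))
    assert all(r.outcome == POSITIVE_LABEL for r in rs.rules)
    assert rs.default_class == NEGATIVE_LABEL
    # flipped imbalance: rules should target the negative class instead
    t2 = make_table(x, 1 - y, ["x"])
    rs2 = ripper_train(t2, RipperParams(seed=0))
    assert all(r.outcome == NEGATIVE_LABEL for r in rs2.rules)
    assert rs2.default_class == POSITIVE_LABEL


def test_min_covered_honored(small_signal_table):
    table, _ = small_signal_table
    params = RipperParams(seed=1, min_covered=5)
    rs = ripper_train(table, params)
    col = {n: j for j, n in enumerate(table.feature_names)}
    for rule in rs.rules:
        mask = np.ones(table.n_samples, dtype=bool)
        for c in rule.conditions:
            v = table.values[:, col[c.feature_name]]
            mask &= (v <= c.threshold) if c.relation == "<=" else (v >= c.threshold)
        assert mask.sum() >= params.min_covered


def test_single_class_rejected():
    t = make_table([[1.0], [2.0]], [1, 1])
    with pytest.raises(ValueError):
        ripper_train(t)


def test_empty_table_rejected():
    t = make_table(np.empty((0, 1)), [])
    with pytest.raises(ValueError):
        ripper_train(t)


def test_params_validation():
    for bad in (
        dict(prune_fraction=0.0),
        dict(prune_fraction=1.0),
        dict(min_covered=0),
        dict(optimization_passes=-1),
        dict(dl_slack_bits=0),
    ):
        with pytest.raises(ValueError):
            RipperParams(**bad)


def test_description_length_monotone_in_errors():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, (100, 2))
    t_good = X[:, 0] <= 0.5
    rules = [((0, "<=", 0.5),)]
    dl_good = ruleset_description_length(rules, X, t_good, 50)
    # same rule, scrambled targets -> more exceptions -> longer DL
    t_bad = rng.random(100) < 0.5
    dl_bad = ruleset_description_length(rules, X, t_bad, 50)
    assert dl_bad > dl_good
    # adding a useless rule can only increase theory bits for identical data
    dl_two = ruleset_description_length(rules + [((1, "<=", 0.99),)], X, t_good, 50)
    assert dl_two > dl_good
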
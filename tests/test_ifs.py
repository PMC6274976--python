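import numpy as np
import pytest

from exprules.ifs import (
    IFSCurve,
    NullDistribution,
    first_crossing,
    null_boxplot_summary,
    optimal_point,
    random_subset_null,
    run_ifs,
    sigma_excess,
)
from exprules.model_eval import ClassifierSpec, MetricSet
from exprules.mrmr import RankedFeatureList, mrmr_rank



def curve_from_mccs(mccs):
    spec = ClassifierSpec("one_nn")
    points = tuple(
        (i + 1, MetricSet(SN=0.5, SP=0.5, ACC=0.5, MCC=float(m))) for i, m in enumerate(mccs)
    )
    return IFSCurve(points=points, classifier=spec)


# ---------------------------------------------------------------------------
# curve bookkeeping
# ---------------------------------------------------------------------------

def test_curve_rejects_unsorted_sizes():
    spec = ClassifierSpec("one_nn")
    m = MetricSet(0.5, 0.5, 0.5, 0.0)
    with pytest.raises(ValueError):
        IFSCurve(points=((2, m), (1, m)), classifier=spec)


def test_optimal_point_tie_breaks_small():
    assert optimal_point(curve_from_mccs([0.5, 0.7, 0.7]))[0] == 2


def test_optimal_point_increasing():
    assert optimal_point(curve_from_mccs([0.1, 0.2, 0.9]))[0] == 3


def test_optimal_point_matches_scan():
    rng = np.random.default_rng(17)
    for _ in range(30):
        mccs = rng.uniform(-1, 1, 15)
        curve = curve_from_mccs(mccs)
        size, metrics = optimal_point(curve)
        assert metrics.MCC == pytest.approx(mccs.max())
        assert size == int(np.argmax(mccs)) + 1


def test_first_crossing_cases():
    curve = curve_from_mccs([0.2, 0.9])
    assert first_crossing(curve, 0.88) == 2
    assert first_crossing(curve, 1.1) is None
    assert first_crossing(curve, 0.2) == 1


def test_first_crossing_monotone_in_threshold():
    rng = np.random.default_rng(5)
    for _ in range(20):
        mccs = np.sort(rng.uniform(0, 1, 10))
        curve = curve_from_mccs(mccs)
        prev = 0
        for t in np.linspace(0, 1, 15):
            got = first_crossing(curve, t)
            if got is None:
                break
            assert got >= prev
            prev = got


def test_first_crossing_at_optimal_not_after():
    rng = np.random.default_rng(9)
    mccs = rng.uniform(-1, 1, 12)
    curve = curve_from_mccs(mccs)
    size, metrics = optimal_point(curve)
    assert first_crossing(curve, metrics.MCC) <= size


def test_empty_curve_errors():
    curve = IFSCurve(points=(), classifier=ClassifierSpec("one_nn"))
    with pytest.raises(ValueError):
        optimal_point(curve)
    with pytest.raises(ValueError):
        first_crossing(curve, 0.5)


# ---------------------------------------------------------------------------
# run_ifs
# ---------------------------------------------------------------------------

def test_run_ifs_single_feature(separable_table):
    ranking = mrmr_rank(separable_table)
    curve = run_ifs(separable_table, ranking, ClassifierSpec("one_nn"), k=4, seed=0)
    assert len(curve.points) == 1
    assert curve.points[0][0] == 1


def test_run_ifs_locality(small_signal_table):
    # curve prefix must not depend on features ranked after max_size
    table, _ = small_signal_table
    ranking = mrmr_rank(table)
    spec = ClassifierSpec("logistic", seed=0)
    full = run_ifs(table, ranking, spec, k=4, seed=0, max_size=4)
    # scramble the tail of the ranking: same prefix, different suffix
    tail = list(ranking.order[4:])[::-1]
    scrambled = RankedFeatureList(
        order=tuple(list(ranking.order[:4]) + tail),
        scores=ranking.scores,
        criterion=ranking.criterion,
    )
    again = run_ifs(table, scrambled, spec, k=4, seed=0, max_size=4)
    assert [m.MCC for _, m in full.points] == [m.MCC for _, m in again.points]


def test_run_ifs_validation(small_signal_table):
    table, _ = small_signal_table
    ranking = mrmr_rank(table)
    with pytest.raises(ValueError):
        run_ifs(table, ranking, ClassifierSpec("one_nn"), max_size=table.n_features + 1)
    bad = RankedFeatureList(
        order=tuple(range(table.n_features - 1)),
        scores=tuple(0.0 for _ in range(table.n_features - 1)),
        criterion="mrmr",
    )
    with pytest.raises(ValueError):
        run_ifs(table, bad, ClassifierSpec("one_nn"))


def test_run_ifs_stride(small_signal_table):
    table, _ = small_signal_table
    ranking = mrmr_rank(table)
    curve = run_ifs(table, ranking, ClassifierSpec("logistic"), k=4, seed=0, stride=5)
    sizes = [i for i, _ in curve.points]
    assert sizes[0] == 1 and sizes[-1] == table.n_features


# ---------------------------------------------------------------------------
# null distribution and sigma excess
# ---------------------------------------------------------------------------

def test_null_degenerate_full_subset(small_signal_table):
    table, _ = small_signal_table
    null = random_subset_null(
        table,
        anchor=table.feature_names[0],
        subset_size=table.n_features,
        spec=ClassifierSpec("logistic", seed=0),
        n_iter=3,
        k=4,
        seed=0,
    )
    assert null.sd == pytest.approx(0.0, abs=1e-12)
    assert len(set(null.mccs)) == 1


def test_null_deterministic(small_signal_table):
    table, _ = small_signal_table
    kwargs = dict(
        anchor=table.feature_names[0],
        subset_size=4,
        spec=ClassifierSpec("one_nn", seed=0),
        n_iter=5,
        k=4,
        seed=11,
    )
    a = random_subset_null(table, **kwargs)
    b = random_subset_null(table, **kwargs)
    assert a == b


def test_null_mean_sd_recomputable(small_signal_table):
    table, _ = small_signal_table
    null = random_subset_null(
        table,
        anchor=table.feature_names[0],
        subset_size=4,
        spec=ClassifierSpec("logistic", seed=0),
        n_iter=8,
        k=4,
        seed=2,
    )
    arr = np.array(null.mccs)
    assert null.mean == pytest.approx(arr.mean(), abs=1e-15)
    assert null.sd == pytest.approx(arr.std(ddof=1), abs=1e-15)


def test_null_validation(small_signal_table):
    table, _ = small_signal_table
    spec = ClassifierSpec("one_nn")
    with pytest.raises(ValueError):
        random_subset_null(table, "nope", 4, spec, n_iter=1)
    with pytest.raises(ValueError):
        random_subset_null(table, table.feature_names[0], 1, spec, n_iter=1)
    with pytest.raises(ValueError):
        random_subset_null(table, table.feature_names[0], table.n_features + 1, spec, n_iter=1)
    with pytest.raises(ValueError):
        random_subset_null(table, table.feature_names[0], 4, spec, n_iter=0)


def test_sigma_excess_published_values():
    null = NullDistribution(
        mccs=(0.86,), mean=0.860, sd=0.015, anchor_feature="a", subset_size=13, seed=0
    )
    assert sigma_excess(0.880, null) == pytest.approx(4.0 / 3.0, abs=1e-9)
    null2 = NullDistribution(
        mccs=(0.847,), mean=0.847, sd=0.015, anchor_feature="a", subset_size=10, seed=0
    )
    assert sigma_excess(0.876, null2) == pytest.approx(29.0 / 15.0, abs=1e-9)
    assert sigma_excess(0.860, null) == 0.0


def test_sigma_excess_zero_sd():
    null = NullDistribution(mccs=(0.5,), mean=0.5, sd=0.0, anchor_feature="a", subset_size=2, seed=0)
    with pytest.raises(ValueError):
        sigma_excess(0.6, null)


def test_boxplot_summary_consistent():
    rng = np.random.default_rng(3)
    mccs = tuple(float(v) for v in rng.normal(0.5, 0.1, 200))
    arr = np.array(mccs)
    null = NullDistribution(
        mccs=mccs,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        anchor_feature="a",
        subset_size=5,
        seed=0,
    )
    s = null_boxplot_summary(null)
    assert s["q1"] <= s["median"] <= s["q3"]
    assert s["min"] <= s["whisker_low"] <= s["q1"]
    assert s["q3"] <= s["whisker_high"] <= s["max"]
    assert s["median"] == pytest.approx(np.median(arr))
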
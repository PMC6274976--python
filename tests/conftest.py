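import numpy as np
import pytest

from exprules.feature_table import FeatureTable


def make_table(values, labels, feature_names=None, ids=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, 1)
    n, m = values.shape
    return FeatureTable(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        labels=np.asarray(labels, dtype=int),
        feature_names=feature_names or [f"f{j}" for j in range(m)],
        values=values,
    )


@pytest.fixture
def duplicate_toy():
    """Noisy class-copy A, its duplicate B, and independent noise C.

    A carries class signal with ~10% flips so the duplicate's redundancy
    penalty (-H(A|y)) is strictly worse than noise under the mRMR criterion.
    """
    rng = np.random.default_rng(7)
    n = 300
    y = (rng.random(n) < 0.3).astype(int)
    flip = rng.random(n) < 0.1
    a = np.where(flip, 1 - y, y).astype(float)
    A = a * 10 + rng.uniform(0, 0.1, n)
    B = A + rng.uniform(0, 0.01, n)
    C = rng.uniform(0, 1, n)
    return make_table(np.column_stack([A, B, C]), y, ["A", "B", "C"])


@pytest.fixture
def separable_table():
    """Separable single-feature table with a wide margin: positive iff x < 0.5."""
    rng = np.random.default_rng(3)
    # gridded values so every fold's training set sees each distinct value
    x = np.r_[np.tile([0.1, 0.2, 0.3], 20), np.tile([0.7, 0.8, 0.9], 20)]
    y = np.r_[np.ones(60, int), np.zeros(60, int)]
    perm = rng.permutation(120)
    return make_table(x[perm], y[perm], ["x"])


@pytest.fixture(scope="session")
def small_signal_table():
    """Quick planted-signal table for CV-level tests."""
    from exprules.synthetic import SyntheticSpec, generate_table

    spec = SyntheticSpec(
        n_pos=120,
        n_neg=160,
        n_facets=12,
        n_informative=4,
        effect_log2=4.0,
        dropout_pos=0.5,
        dropout_neg=0.15,
        seed=11,
    )
    table, informative = generate_table(spec)
    return table, informative
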
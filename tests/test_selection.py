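"""Feature scaling, ranking methods and the PCA resultant procedure."""

import numpy as np
import pytest

from falladl.features import FeatureMatrix, N_FEATURES
from falladl.selection import (
    MethodError,
    RankingResult,
    SelectionConfigError,
    apply_minmax,
    available_methods,
    pca_rank,
    rank,
    register_ranker,
    relieff_scores,
    scale_minmax,
)
from oracles import relieff_oracle


def _fm(values, labels, datasets=None):
    """Wrap a small matrix into a FeatureMatrix, padding to 199 columns."""
    values = np.asarray(values, float)
    w, f = values.shape
    full = np.zeros((w, N_FEATURES))
    full[:, :f] = values
    if datasets is None:
        datasets = np.array(["d0"] * w, dtype=object)
    return FeatureMatrix(
        values=full, labels=np.asarray(labels),
        subject_ids=np.array(["s"] * w, dtype=object),
        dataset_ids=np.asarray(datasets, dtype=object),
    )


# ---------------------------------------------------------------------------
# scaling

def test_minmax_maps_column_to_unit_interval():
    fm = scale_minmax(_fm([[2.0], [4.0], [6.0]], [0, 1, 0]), grouping="train_fit")
    np.testing.assert_allclose(fm.values[:, 0], [0.0, 0.5, 1.0])


def test_constant_column_maps_to_zero():
    fm = scale_minmax(_fm([[5.0], [5.0]], [0, 1]), grouping="train_fit")
    assert (fm.values[:, 0] == 0.0).all()


def test_per_dataset_grouping_scales_each_dataset_separately():
    values = [[1.0], [3.0], [1.0], [5.0]]
    ds = ["a", "a", "b", "b"]
    fm = scale_minmax(_fm(values, [0, 1, 0, 1], ds), grouping="per_dataset")
    # the same raw value 3.0-equivalent position differs across datasets
    np.testing.assert_allclose(fm.values[:, 0], [0.0, 1.0, 0.0, 1.0])


def test_double_scaling_rejected():
    fm = scale_minmax(_fm([[1.0], [2.0]], [0, 1]), grouping="train_fit")
    with pytest.raises(ValueError):
        scale_minmax(fm)


def test_unknown_grouping_rejected():
    with pytest.raises(SelectionConfigError):
        scale_minmax(_fm([[1.0], [2.0]], [0, 1]), grouping="global")


def test_train_fit_parameters_transform_unseen_data():
    train = scale_minmax(_fm([[0.0], [10.0]], [0, 1]), grouping="train_fit")
    test = apply_minmax(_fm([[5.0], [20.0]], [0, 1]), train.scaling_params)
    assert test.values[0, 0] == pytest.approx(0.5)
    assert test.values[1, 0] == 1.0       # clipped to the training range


def test_scaled_values_lie_in_unit_interval(rng):
    fm = _fm(rng.normal(0, 50, (30, 10)), rng.integers(0, 3, 30))
    out = scale_minmax(fm, grouping="train_fit")
    assert out.values.min() >= 0.0 and out.values.max() <= 1.0


# ---------------------------------------------------------------------------
# ranking: generic contracts

def _separable_fm(rng, n=120, n_feat=13, n_informative=3):
    """Classes split by the first features; the rest is pure noise."""
    y = rng.integers(0, 3, n)
    X = rng.normal(0, 1, (n, n_feat))
    for j in range(n_informative):
        X[:, j] = y * 3.0 + rng.normal(0, 0.1, n)
    fm = _fm(X, y)
    fm.values[:, n_feat:N_FEATURES] = rng.normal(0, 1, (n, N_FEATURES - n_feat))
    return scale_minmax(fm, grouping="train_fit")


@pytest.mark.parametrize("method", ["relieff", "mutinf", "mrmr", "cfs", "lasso"])
def test_ranking_returns_a_full_permutation(method, rng):
    fm = _separable_fm(rng)
    res = rank(fm, method, seed=0)
    assert sorted(res.order.tolist()) == list(range(1, N_FEATURES + 1))


@pytest.mark.parametrize("method", ["relieff", "mutinf", "mrmr", "cfs"])
def test_informative_features_outrank_noise(method, rng):
    fm = _separable_fm(rng)
    res = rank(fm, method, seed=0)
    assert set(res.order[:3].tolist()) <= set(range(1, 6))


def test_single_class_input_rejected(rng):
    fm = scale_minmax(_fm(rng.normal(size=(10, 3)), [2] * 10), "train_fit")
    with pytest.raises(MethodError):
        rank(fm, "relieff")


def test_unscaled_input_rejected(rng):
    fm = _fm(rng.normal(size=(10, 3)), [0, 1] * 5)
    with pytest.raises(ValueError):
        rank(fm, "relieff")


def test_unknown_method_rejected(rng):
    fm = scale_minmax(_fm(rng.normal(size=(10, 3)), [0, 1] * 5), "train_fit")
    with pytest.raises(SelectionConfigError):
        rank(fm, "chi2")


def test_plugin_rankers_can_be_registered(rng):
    fm = scale_minmax(_fm(rng.normal(size=(10, 3)), [0, 1] * 5), "train_fit")

    def reversed_ranker(fm, seed):
        f = fm.values.shape[1]
        return RankingResult("reversed", np.arange(f, 0, -1), np.zeros(f))

    register_ranker("reversed", reversed_ranker)
    assert "reversed" in available_methods()
    assert rank(fm, "reversed").order[0] == N_FEATURES


def test_ranking_result_rejects_non_permutations():
    with pytest.raises(ValueError):
        RankingResult("x", np.array([1, 1, 3]), np.zeros(3))


# ---------------------------------------------------------------------------
# Relief-F specifics

def test_relieff_matches_quadratic_oracle_exactly(rng):
    X = rng.random((60, 7))
    y = rng.integers(0, 3, 60)
    np.testing.assert_allclose(relieff_scores(X, y), relieff_oracle(X, y),
                               rtol=0, atol=1e-12)


def test_duplicated_columns_share_scores_with_id_tie_break(rng):
    X = rng.random((40, 1))
    X = np.hstack([X, X, rng.random((40, 1))])
    y = rng.integers(0, 2, 40)
    fm = scale_minmax(_fm(X, y), "train_fit")
    res = rank(fm, "relieff")
    assert res.scores[0] == pytest.approx(res.scores[1], abs=1e-12)
    assert list(res.order).index(1) < list(res.order).index(2)


# ---------------------------------------------------------------------------
# PCA resultant procedure

def _pca_fm(values, labels=None):
    """FeatureMatrix with exactly the given columns (no padding)."""
    values = np.asarray(values, float)
    w = values.shape[0]
    if labels is None:
        labels = np.zeros(w, dtype=int)
    fm = FeatureMatrix.__new__(FeatureMatrix)
    fm.values = values
    fm.labels = np.asarray(labels)
    fm.subject_ids = np.array(["s"] * w, dtype=object)
    fm.dataset_ids = np.array(["d"] * w, dtype=object)
    fm.descriptors = ()
    fm.scaling_state = "minmax_train_fit"
    fm.scaling_params = {}
    return fm


def test_two_feature_analytic_case_keeps_one_component(rng):
    n = 4000
    X = np.column_stack([rng.normal(0, 3.0, n), rng.normal(0, 1.0, n)])
    out = pca_rank(_pca_fm(X))
    assert out.n_components == 1          # PC1 explains ~90% >= 70%
    assert out.order[0] == 1              # high-variance feature ranks first


def test_exactly_uniform_resultant_loading_fails_the_strict_threshold(rng):
    x = rng.normal(size=200)
    X = np.column_stack([x, x])           # PC1 loading (1/sqrt2, 1/sqrt2)
    out = pca_rank(_pca_fm(X))
    np.testing.assert_allclose(out.resultant_loading, [0.5, 0.5], atol=1e-12)
    assert out.n_above_uniform == 0 and out.cap == 0


def test_resultant_loading_is_a_distribution_and_cap_is_doubled_count(rng):
    X = rng.random((500, 20)) * rng.random(20)
    out = pca_rank(_pca_fm(X))
    assert out.resultant_loading.sum() == pytest.approx(1.0, abs=1e-12)
    assert (out.resultant_loading >= 0).all()
    assert out.cap == 2 * out.n_above_uniform
    assert out.cum_explained >= 0.70


def test_pca_rank_invariant_to_row_order(rng):
    X = rng.random((300, 12))
    perm = rng.permutation(300)
    a = pca_rank(_pca_fm(X))
    b = pca_rank(_pca_fm(X[perm]))
    np.testing.assert_allclose(a.resultant_loading, b.resultant_loading, atol=1e-9)
    assert a.n_components == b.n_components and a.cap == b.cap


def test_zero_variance_matrix_rejected():
    with pytest.raises(MethodError):
        pca_rank(_pca_fm(np.ones((50, 4))))
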
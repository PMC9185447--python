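"""Hold-out, cross-validation, metrics, grid search and window study."""

import numpy as np
import pytest

from falladl.benchmark import (
    BenchmarkConfigError,
    DEFAULT_SPECS,
    ENSEMBLE_GRID,
    KNN_GRID,
    ModelSpec,
    SplitPlan,
    _inverse_weights,
    _stratified_folds,
    build_model,
    compute_metrics,
    final_test,
    gridsearch,
    make_holdout,
    multiclass_mcc,
    progressive_sweep,
    run_cv,
)
from falladl.features import FeatureMatrix, N_FEATURES
from falladl.selection import RankingResult
from falladl.taxonomy import N_CLASSES
from oracles import mcc_oracle


def _fm(values, labels, subjects=None, datasets=None):
    values = np.asarray(values, float)
    w, f = values.shape
    full = np.zeros((w, N_FEATURES))
    full[:, :f] = values
    return FeatureMatrix(
        values=full, labels=np.asarray(labels),
        subject_ids=np.asarray(subjects if subjects is not None else ["s"] * w,
                               dtype=object),
        dataset_ids=np.asarray(datasets if datasets is not None else ["d"] * w,
                               dtype=object),
        scaling_state="minmax_train_fit",
    )


def _identity_ranking(f=N_FEATURES):
    return RankingResult("identity", np.arange(1, f + 1), np.zeros(f))


def _clusters_fm(rng, n_per=40, n_classes=4, spread=0.05):
    """Trivially separable Gaussian clusters in the first two features."""
    centers = rng.uniform(0, 1, (n_classes, 2))
    rows, labels = [], []
    for c in range(n_classes):
        rows.append(centers[c] + rng.normal(0, spread, (n_per, 2)))
        labels += [c] * n_per
    return _fm(np.vstack(rows), labels)


# ---------------------------------------------------------------------------
# hold-out splits

def test_seventy_thirty_split_counts(rng):
    fm = _fm(rng.random((1000, 2)), rng.integers(0, 2, 1000))
    # force exact class sizes that divide evenly
    fm.labels[:500] = 0
    fm.labels[500:] = 1
    plan = make_holdout(fm, seed=0)
    assert len(plan.train_idx) == 700 and len(plan.test_idx) == 300


def test_split_is_deterministic_per_seed(rng):
    fm = _fm(rng.random((100, 2)), rng.integers(0, 3, 100))
    a, b = make_holdout(fm, seed=5), make_holdout(fm, seed=5)
    np.testing.assert_array_equal(a.train_idx, b.train_idx)
    c = make_holdout(fm, seed=6)
    assert not np.array_equal(a.train_idx, c.train_idx)


def test_stratification_keeps_per_class_fraction_within_one_window(rng):
    labels = np.concatenate([np.full(37, 0), np.full(11, 1), np.full(52, 2)])
    fm = _fm(rng.random((100, 2)), labels)
    plan = make_holdout(fm, ratio=0.7, seed=1)
    for c, size in ((0, 37), (1, 11), (2, 52)):
        n_train = int((fm.labels[plan.train_idx] == c).sum())
        assert abs(n_train - 0.7 * size) <= 1.0


def test_single_window_class_goes_to_train_with_warning(rng):
    labels = np.array([0] * 20 + [1])
    fm = _fm(rng.random((21, 2)), labels)
    with pytest.warns(UserWarning, match="single window"):
        plan = make_holdout(fm, seed=0)
    assert 20 in plan.train_idx


def test_subjectwise_split_keeps_whole_subjects_together(rng):
    subjects = np.repeat([f"p{i}" for i in range(10)], 10)
    fm = _fm(rng.random((100, 2)), rng.integers(0, 2, 100), subjects=subjects)
    plan = make_holdout(fm, mode="subjectwise", seed=0)
    train_subj = set(fm.subject_ids[plan.train_idx])
    test_subj = set(fm.subject_ids[plan.test_idx])
    assert not (train_subj & test_subj)


def test_overlapping_split_plan_rejected():
    with pytest.raises(ValueError):
        SplitPlan(train_idx=np.array([0, 1]), test_idx=np.array([1, 2]))


# ---------------------------------------------------------------------------
# metrics

def test_perfect_confusion_scores_100_everywhere():
    rep = compute_metrics(np.diag([5] * 4))
    for m in ("ACC", "Sens", "Spec", "Prec", "F1S", "MCC"):
        assert rep.macro[m] == pytest.approx(100.0)


def test_truth_independent_predictions_have_zero_mcc():
    assert multiclass_mcc(np.array([[25, 25], [25, 25]])) == pytest.approx(0.0)


def test_multiclass_mcc_matches_direct_formula(rng):
    for _ in range(20):
        k = int(rng.integers(2, 8))
        C = rng.integers(0, 40, (k, k))
        assert multiclass_mcc(C) == pytest.approx(mcc_oracle(C), abs=1e-12)


def test_per_class_metrics_match_brute_force_tally(rng):
    C = rng.integers(0, 25, (5, 5))
    rep = compute_metrics(C)
    total = C.sum()
    for c in range(5):
        tp = C[c, c]
        fn = C[c].sum() - tp
        fp = C[:, c].sum() - tp
        tn = total - tp - fn - fp
        assert rep.per_class["Sens"][c] == pytest.approx(
            100 * tp / (tp + fn) if tp + fn else 0.0)
        assert rep.per_class["Spec"][c] == pytest.approx(100 * tn / (tn + fp))
    assert rep.macro["ACC"] == pytest.approx(100 * np.trace(C) / total)


def test_macro_values_are_unweighted_class_means(rng):
    rep = compute_metrics(rng.integers(0, 30, (6, 6)))
    for m in ("Sens", "Spec", "Prec", "F1S"):
        assert rep.macro[m] == pytest.approx(rep.per_class[m].mean())


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        compute_metrics(np.array([[1, -1], [0, 2]]))


# ---------------------------------------------------------------------------
# models

def test_unknown_model_rejected():
    with pytest.raises(BenchmarkConfigError):
        ModelSpec("svm")


def test_default_model_configurations_lie_on_the_search_grids():
    knn = ModelSpec("knn").resolved()
    assert knn == {"n_neighbors": 1, "distance": "minkowski", "exponent": 0.5,
                   "weighting": "squared_inverse"}
    bag = ModelSpec("ensemble_bag").resolved()
    assert bag == {"method": "bag", "n_cycles": 37}
    assert {"n_neighbors": 1, "distance": "minkowski", "exponent": 0.5,
            "weighting": "squared_inverse"} in KNN_GRID
    assert {"method": "bag", "n_cycles": 37} in ENSEMBLE_GRID


def test_fractional_minkowski_knn_fits_and_predicts(rng):
    est = build_model(ModelSpec("knn"))
    X, y = rng.random((30, 4)), rng.integers(0, 3, 30)
    with pytest.warns(UserWarning):   # p < 1 is a dissimilarity, not a metric
        est.fit(X, y)
        pred = est.predict(X)
    assert (pred == y).all()          # 1-NN with exact matches is perfect


def test_zero_distance_neighbors_take_all_weight():
    weigh = _inverse_weights(2.0)
    w = weigh(np.array([[0.0, 1.0, 2.0], [1.0, 2.0, 4.0]]))
    np.testing.assert_allclose(w[0], [1.0, 0.0, 0.0])
    np.testing.assert_allclose(w[1], [1.0, 0.25, 1.0 / 16.0])


# ---------------------------------------------------------------------------
# cross-validation

def test_stratified_folds_partition_every_index_once(rng):
    y = rng.integers(0, 4, 83)
    folds = _stratified_folds(y, 5, np.random.default_rng(0))
    all_idx = np.concatenate(folds)
    assert sorted(all_idx.tolist()) == list(range(83))


def test_repeated_cv_reports_mean_and_std(rng):
    fm = _clusters_fm(rng)
    rep = run_cv(fm, ModelSpec("dtree"), _identity_ranking(), 2, repeats=3, seed=0)
    assert rep.std is not None and set(rep.std) == {"ACC", "Sens", "Spec",
                                                    "Prec", "F1S", "MCC"}
    rep1 = run_cv(fm, ModelSpec("dtree"), _identity_ranking(), 2, repeats=1, seed=0)
    assert rep1.std is None


def test_cv_on_separable_clusters_is_near_perfect(rng):
    fm = _clusters_fm(rng, spread=0.01)
    rep = run_cv(fm, ModelSpec("knn"), _identity_ranking(), 2, seed=0)
    assert rep.macro["ACC"] > 99.0


def test_too_many_features_rejected(rng):
    fm = _clusters_fm(rng)
    with pytest.raises(BenchmarkConfigError):
        run_cv(fm, ModelSpec("knn"), _identity_ranking(), N_FEATURES + 1)


# ---------------------------------------------------------------------------
# sweep and grid search

def test_sweep_with_single_candidate_returns_it(rng):
    fm = _clusters_fm(rng)
    res = progressive_sweep(fm, [ModelSpec("dtree")], [_identity_ranking()],
                            cap=3, stride=3, seed=0)
    assert res.best_n[("dtree", "identity")] == 3


def test_sweep_best_never_exceeds_cap(rng):
    fm = _clusters_fm(rng)
    res = progressive_sweep(fm, [ModelSpec("dtree")], [_identity_ranking()],
                            cap=4, stride=2, seed=0)
    assert res.best_n[("dtree", "identity")] <= 4
    assert len(res.entries) == 2


def test_sweep_without_models_rejected(rng):
    with pytest.raises(BenchmarkConfigError):
        progressive_sweep(_clusters_fm(rng), [], [_identity_ranking()], cap=4)


def test_gridsearch_returns_an_element_of_the_declared_grid(rng):
    fm = _clusters_fm(rng, n_per=15)
    spec = gridsearch(fm, "knn", _identity_ranking(), 2, seed=0)
    assert spec.resolved() in KNN_GRID
    lda = gridsearch(fm, "lda", _identity_ranking(), 2, seed=0)
    assert lda.model_id == "lda"


# ---------------------------------------------------------------------------
# final hold-out test

def test_separable_clusters_reach_perfect_holdout_accuracy(rng):
    fm = _clusters_fm(rng, spread=0.01)
    plan = make_holdout(fm, seed=0)
    rep = final_test(fm, plan, ModelSpec("knn"), _identity_ranking(), 2, seed=0)
    assert rep.macro["ACC"] == pytest.approx(100.0)
    assert set(rep.macro) == {"ACC", "Sens", "Spec", "Prec", "F1S", "MCC"}


def test_timing_fields_are_consistent(rng):
    fm = _clusters_fm(rng)
    plan = make_holdout(fm, seed=0)
    rep = final_test(fm, plan, ModelSpec("dtree"), _identity_ranking(), 2, seed=0)
    assert rep.test_time_per_window_s == pytest.approx(
        rep.test_time_s / len(plan.test_idx))
    assert rep.train_time_s >= 0.0


def test_confusion_row_sums_equal_true_class_counts(rng):
    fm = _clusters_fm(rng)
    plan = make_holdout(fm, seed=0)
    rep = final_test(fm, plan, ModelSpec("dtree"), _identity_ranking(), 2, seed=0)
    true_counts = np.bincount(fm.labels[plan.test_idx], minlength=N_CLASSES)
    np.testing.assert_array_equal(rep.confusion.sum(axis=1), true_counts)
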
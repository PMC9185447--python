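"""Progressive classifier-benchmarking protocol.

The comparative protocol: a stratified 70/30 hold-out split; a
progressive feature-count sweep under 5-fold cross-validation on the
training partition only, for every (classifier, feature-selection
method) pair up to the PCA-derived cap; repeated (10x) CV for the best
candidates; hyperparameter grid search; a final fit on all training
data evaluated once on the untouched test partition; and a window-size
study re-running the whole pipeline at 0.5/1/1.5/2 s windows.

Metrics: per-class one-vs-rest sensitivity, specificity, precision and
F1 plus their unweighted macro means, overall accuracy, and the
multiclass (Gorodkin) Matthews correlation coefficient on the full
confusion matrix, all reported in percent. Timing is measured with a
monotonic clock and reported, never asserted.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from falladl.features import FeatureMatrix, SCALING_RAW
from falladl.selection import RankingResult, apply_minmax, scale_minmax
from falladl.taxonomy import N_CLASSES

METRIC_NAMES = ("ACC", "Sens", "Spec", "Prec", "F1S", "MCC")


class BenchmarkConfigError(ValueError):
    """Unknown model or invalid benchmarking option."""


# ---------------------------------------------------------------------------
# split plans

@dataclass
class SplitPlan:
    """Disjoint train/test window-index sets."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    mode: str = "windowwise_stratified"
    seed: int = 0
    ratio: float = 0.70

    def __post_init__(self) -> None:
        tr, te = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


def make_holdout(fm: FeatureMatrix, ratio: float = 0.70,
                 mode: str = "windowwise_stratified", seed: int = 0) -> SplitPlan:
    """Deterministic hold-out split.

    ``windowwise_stratified`` keeps per-class train fractions within
    +-1 window of the ratio (classes with a single window go to train,
    with a warning). ``subjectwise`` assigns whole subjects to one side,
    greedily approximating the ratio on window counts.
    """
    rng = np.random.default_rng(seed)
    n = fm.n_windows
    if mode == "windowwise_stratified":
        train, test = [], []
        for c in np.unique(fm.labels):
            idx = np.flatnonzero(fm.labels == c)
            if idx.size == 1:
                warnings.warn(f"class {c} has a single window; assigned to train",
                              stacklevel=2)
                train.extend(idx.tolist())
                continue
            perm = rng.permutation(idx)
            n_train = int(round(ratio * idx.size))
            train.extend(perm[:n_train].tolist())
            test.extend(perm[n_train:].tolist())
    elif mode == "subjectwise":
        # subjects are unique within a source dataset; key on both
        keys = np.array([f"{d}/{s}" for d, s in zip(fm.dataset_ids, fm.subject_ids)])
        subjects = rng.permutation(np.unique(keys))
        train, test = [], []
        n_train_target = ratio * n
        assigned = 0
        for subj in subjects:
            idx = np.flatnonzero(keys == subj)
            if assigned < n_train_target:
                train.extend(idx.tolist())
                assigned += idx.size
            else:
                test.extend(idx.tolist())
    else:
        raise BenchmarkConfigError(f"unknown split mode {mode!r}")
    return SplitPlan(
        train_idx=np.sort(np.array(train, dtype=int)),
        test_idx=np.sort(np.array(test, dtype=int)),
        mode=mode, seed=seed, ratio=ratio,
    )


# ---------------------------------------------------------------------------
# models

DEFAULT_SPECS = {
    "lda": {},
    "qda": {"reg_param": 0.0},
    "knn": {"n_neighbors": 1, "distance": "minkowski", "exponent": 0.5,
            "weighting": "squared_inverse"},
    "ensemble_bag": {"method": "bag", "n_cycles": 37},
    "dtree": {},
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier identity plus hyperparameters from the declared grids."""

    model_id: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in DEFAULT_SPECS:
            raise BenchmarkConfigError(f"unknown model {self.model_id!r}")

    def resolved(self) -> dict:
        hp = dict(DEFAULT_SPECS[self.model_id])
        hp.update(self.hyperparameters)
        return hp


def _inverse_weights(power: float):
    def weigh(dist: np.ndarray) -> np.ndarray:
        dist = np.asarray(dist, float)
        zero = dist <= 1e-12
        out = np.empty_like(dist)
        with np.errstate(divide="ignore"):
            out = 1.0 / np.maximum(dist, 1e-300) ** power
        # exact matches take all the weight in their row
        rows = zero.any(axis=1)
        out[rows] = zero[rows].astype(float)
        return out
    return weigh


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a model spec."""
    hp = spec.resolved()
    if spec.model_id == "lda":
        return LinearDiscriminantAnalysis()
    if spec.model_id == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=hp["reg_param"])
    if spec.model_id == "knn":
        weighting = hp["weighting"]
        if weighting == "uniform":
            weights = "uniform"
        elif weighting == "inverse":
            weights = _inverse_weights(1.0)
        elif weighting == "squared_inverse":
            weights = _inverse_weights(2.0)
        else:
            raise BenchmarkConfigError(f"unknown knn weighting {weighting!r}")
        distance = hp["distance"]
        kwargs = dict(n_neighbors=hp["n_neighbors"], weights=weights)
        if distance == "euclidean":
            kwargs.update(metric="euclidean")
        elif distance == "cityblock":
            kwargs.update(metric="manhattan")
        elif distance == "minkowski":
            p = hp["exponent"]
            kwargs.update(metric="minkowski", p=p)
            if p < 1:
                kwargs.update(algorithm="brute")
        else:
            raise BenchmarkConfigError(f"unknown knn distance {distance!r}")
        return KNeighborsClassifier(**kwargs)
    if spec.model_id == "ensemble_bag":
        if hp["method"] != "bag":
            raise BenchmarkConfigError("only bagged ensembles are supported")
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=hp["n_cycles"], random_state=seed,
        )
    if spec.model_id == "dtree":
        return DecisionTreeClassifier(random_state=seed)
    raise BenchmarkConfigError(f"unknown model {spec.model_id!r}")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvalReport:
    """Confusion matrix plus percent metrics, per class and macro."""

    confusion: np.ndarray                       # (C, C), rows = truth
    macro: dict                                 # metric name -> percent
    per_class: dict                             # metric name -> (C,) percents
    std: dict | None = None                     # across-repeat std, if repeated
    train_time_s: float | None = None
    test_time_s: float | None = None
    test_time_per_window_s: float | None = None

    def summary(self) -> str:
        parts = []
        for m in METRIC_NAMES:
            if self.std is not None and m in self.std:
                parts.append(f"{m}={self.macro[m]:.2f}±{self.std[m]:.3f}")
            else:
                parts.append(f"{m}={self.macro[m]:.2f}")
        return " ".join(parts)


def multiclass_mcc(confusion: np.ndarray) -> float:
    """Gorodkin's multiclass Matthews correlation coefficient (in [-1, 1])."""
    C = np.asarray(confusion, dtype=float)
    t = C.sum(axis=1)   # true counts per class
    p = C.sum(axis=0)   # predicted counts per class
    s = C.sum()
    c = np.trace(C)
    denom = np.sqrt(s ** 2 - (p ** 2).sum()) * np.sqrt(s ** 2 - (t ** 2).sum())
    if denom == 0:
        return 0.0
    return float((c * s - t @ p) / denom)


def compute_metrics(confusion: np.ndarray) -> EvalReport:
    """Metrics block from a confusion matrix (rows = truth, cols = predicted).

    Per-class values are one-vs-rest; macro values are unweighted class
    means except ACC (overall accuracy, trace/total) and MCC (multiclass
    form on the full matrix). All values are percentages.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = C.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain at least one count")
    tp = np.diag(C)
    fn = C.sum(axis=1) - tp
    fp = C.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def safe(num, den):
        return np.where(den > 0, num / np.maximum(den, 1), 0.0)

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    prec = safe(tp, tp + fp)
    f1 = np.where(prec + sens > 0, 2 * prec * sens / np.where(prec + sens > 0, prec + sens, 1), 0.0)
    acc_cls = (tp + tn) / total
    per_class = {
        "ACC": acc_cls * 100, "Sens": sens * 100, "Spec": spec * 100,
        "Prec": prec * 100, "F1S": f1 * 100,
    }
    macro = {
        "ACC": float(np.trace(C) / total * 100),
        "Sens": float(sens.mean() * 100),
        "Spec": float(spec.mean() * 100),
        "Prec": float(prec.mean() * 100),
        "F1S": float(f1.mean() * 100),
        "MCC": multiclass_mcc(C) * 100,
    }
    return EvalReport(confusion=C, macro=macro, per_class=per_class)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               n_classes: int = N_CLASSES) -> np.ndarray:
    M = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(M, (y_true, y_pred), 1)
    return M


# ---------------------------------------------------------------------------
# cross-validation

def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """k disjoint stratified test folds covering every index exactly once."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        for f in range(k):
            folds[f].extend(idx[f::k].tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def run_cv(fm: FeatureMatrix, model: ModelSpec, ranking: RankingResult,
           n_features: int, k: int = 5, repeats: int = 1,
           seed: int = 0) -> EvalReport:
    """Stratified k-fold CV of one model on the top-n ranked features.

    Each window is tested exactly once per repeat; per-repeat metrics
    are computed from the pooled fold confusion matrix, then averaged
    (mean +- std) across repeats. The returned confusion matrix is the
    sum over repeats. ``fm`` must be the training partition only.
    """
    if n_features > len(ranking.scores):
        raise BenchmarkConfigError(
            f"n_features={n_features} exceeds {len(ranking.scores)} ranked features")
    cols = ranking.top_columns(n_features)
    X = fm.values[:, cols]
    y = np.asarray(fm.labels)
    reports = []
    total_conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        folds = _stratified_folds(y, k, rng)
        for f in range(k):
            test_idx = folds[f]
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            est = build_model(model, seed=seed + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[train_mask], y[train_mask])
                pred = est.predict(X[test_idx])
            conf += _confusion(y[test_idx], pred)
        reports.append(compute_metrics(conf))
        total_conf += conf
    macro = {m: float(np.mean([r.macro[m] for r in reports])) for m in METRIC_NAMES}
    std = None
    if repeats > 1:
        std = {m: float(np.std([r.macro[m] for r in reports])) for m in METRIC_NAMES}
    per_class = {m: np.mean([r.per_class[m] for r in reports], axis=0)
                 for m in reports[0].per_class}
    return EvalReport(confusion=total_conf, macro=macro, per_class=per_class, std=std)


# ---------------------------------------------------------------------------
# progressive sweep

@dataclass
class SweepResult:
    """Grid of CV results over (model, ranking method, feature count)."""

    entries: list                      # dicts: model_id, fsm, n_features, ACC, MCC
    best_n: dict                       # (model_id, fsm) -> argmax-MCC n (ties -> smaller)
    cap: int


def progressive_sweep(fm: FeatureMatrix, models: list[ModelSpec],
                      rankings: list[RankingResult], cap: int,
                      stride: int = 1, k: int = 5, seed: int = 0) -> SweepResult:
    """Evaluate n = stride, 2*stride, ... <= cap for every model x ranking."""
    if not models or not rankings:
        raise BenchmarkConfigError("need at least one model and one ranking")
    ns = list(range(stride, cap + 1, stride))
    if not ns:
        raise BenchmarkConfigError("cap smaller than stride: empty sweep")
    entries = []
    best: dict = {}
    for model in models:
        for ranking in rankings:
            key = (model.model_id, ranking.method)
            best_mcc, best_n = -np.inf, None
            for n in ns:
                rep = run_cv(fm, model, ranking, n, k=k, repeats=1, seed=seed)
                entries.append({
                    "model_id": model.model_id, "fsm": ranking.method,
                    "n_features": n, "ACC": rep.macro["ACC"], "MCC": rep.macro["MCC"],
                })
                if rep.macro["MCC"] > best_mcc:
                    best_mcc, best_n = rep.macro["MCC"], n
            best[key] = best_n
    return SweepResult(entries=entries, best_n=best, cap=cap)


# ---------------------------------------------------------------------------
# grid search

KNN_GRID = [
    {"n_neighbors": nn, "distance": dist, "exponent": p, "weighting": w}
    for nn in (1, 3, 5, 7, 9)
    for dist, p in (("euclidean", 2), ("cityblock", 1),
                    ("minkowski", 0.5), ("minkowski", 3))
    for w in ("uniform", "inverse", "squared_inverse")
]
ENSEMBLE_GRID = [
    {"method": "bag", "n_cycles": n} for n in sorted(set(range(10, 101, 10)) | {37})
]

_GRIDS = {"knn": KNN_GRID, "ensemble_bag": ENSEMBLE_GRID}


def _complexity(model_id: str, hp: dict) -> tuple:
    if model_id == "knn":
        return (hp["n_neighbors"],)
    if model_id == "ensemble_bag":
        return (hp["n_cycles"],)
    return (0,)


def gridsearch(fm: FeatureMatrix, model_id: str, ranking: RankingResult,
               n_features: int, cv: int = 5, seed: int = 0) -> ModelSpec:
    """Exhaustive search over the declared grid, selecting max CV MCC.

    Ties go to the simpler model (fewer neighbors / learning cycles).
    Models without a declared grid return their default spec. ``fm``
    must be the training partition only.
    """
    if model_id not in DEFAULT_SPECS:
        raise BenchmarkConfigError(f"unknown model {model_id!r}")
    grid = _GRIDS.get(model_id, [DEFAULT_SPECS[model_id]])
    best_spec, best_mcc, best_cplx = None, -np.inf, None
    for hp in grid:
        spec = ModelSpec(model_id, dict(hp))
        rep = run_cv(fm, spec, ranking, n_features, k=cv, repeats=1, seed=seed)
        cplx = _complexity(model_id, spec.resolved())
        if (rep.macro["MCC"] > best_mcc
                or (rep.macro["MCC"] == best_mcc and cplx < best_cplx)):
            best_spec, best_mcc, best_cplx = spec, rep.macro["MCC"], cplx
    return best_spec


# ---------------------------------------------------------------------------
# final hold-out evaluation

def final_test(fm: FeatureMatrix, split: SplitPlan, spec: ModelSpec,
               ranking: RankingResult, n_features: int,
               seed: int = 0) -> EvalReport:
    """Train on the full training partition, evaluate once on the test set.

    If ``fm`` is raw, train-fit min-max scaling is fitted on the
    training rows and applied to the test rows (leakage-safe mode);
    otherwise the already-scaled values are used as-is.
    """
    if set(split.train_idx) & set(split.test_idx):
        raise ValueError("train and test indices overlap")
    if fm.scaling_state == SCALING_RAW:
        train_fm = scale_minmax(fm.subset(split.train_idx), grouping="train_fit")
        test_fm = apply_minmax(fm.subset(split.test_idx), train_fm.scaling_params)
    else:
        train_fm = fm.subset(split.train_idx)
        test_fm = fm.subset(split.test_idx)
    cols = ranking.top_columns(n_features)
    est = build_model(spec, seed=seed)
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(train_fm.values[:, cols], train_fm.labels)
    t1 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = est.predict(test_fm.values[:, cols])
    t2 = time.perf_counter()
    report = compute_metrics(_confusion(np.asarray(test_fm.labels), pred))
    report.train_time_s = t1 - t0
    report.test_time_s = t2 - t1
    report.test_time_per_window_s = (t2 - t1) / max(1, test_fm.n_windows)
    return report


# ---------------------------------------------------------------------------
# window-size study

def window_size_study(streams, best_specs,
                      sizes=(0.5, 1.0, 1.5, 2.0), overlap: float = 0.8,
                      scaling_grouping: str = "per_dataset",
                      ratio: float = 0.70, seed: int = 0) -> list[dict]:
    """Re-run the full pipeline at several window sizes.

    ``best_specs`` is a list of ``(ModelSpec, ranking_method, n_features)``
    triples (ranking_method is a :func:`falladl.selection.rank` method
    name or ``"pca"``). For each size, streams are re-segmented,
    features re-extracted and scaled, rankings recomputed on the
    training partition, and each spec evaluated on the hold-out test
    set. Returns one row dict per (size, spec) with the EvalReport.
    """
    from falladl.features import extract_set
    from falladl.segmentation import SegmentationConfig, segment_streams
    from falladl.selection import pca_rank, rank as rank_features

    streams = list(streams)
    rows = []
    for size in sizes:
        cfg = SegmentationConfig(window_s=size, overlap=overlap)
        ws = segment_streams(streams, cfg)
        fm = extract_set(ws)
        fm_scaled = scale_minmax(fm, grouping=scaling_grouping)
        split = make_holdout(fm_scaled, ratio=ratio, seed=seed)
        train = fm_scaled.subset(split.train_idx)
        ranking_cache: dict = {}
        for spec, method, n_feat in best_specs:
            if method not in ranking_cache:
                if method == "pca":
                    ranking_cache[method] = pca_rank(train).as_ranking()
                else:
                    ranking_cache[method] = rank_features(train, method, seed=seed)
            report = final_test(fm_scaled, split, spec, ranking_cache[method],
                                n_feat, seed=seed)
            rows.append({
                "window_s": size, "model_id": spec.model_id, "fsm": method,
                "n_features": n_feat, "report": report,
            })
    return rows
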
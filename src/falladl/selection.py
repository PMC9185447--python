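"""Feature scaling and feature-selection ranking.

Features are min-max scaled to [0, 1] before any ranking, either per
source dataset (replicating the merged-corpus protocol; each dataset is
normalized separately to absorb sensor range and sensitivity
differences) or fitted on the training partition only (leakage-safe
mode for hold-out evaluation).

Implemented rankers: Relief-F, mutual information, mRMR, CFS, LASSO-path
ordering, and a PCA "resultant component" ranking that also yields the
feature-count cap used by the progressive benchmarking sweep: principal
components are accumulated until 70% of the variance is explained, a
variance-weighted resultant of their absolute loadings ranks the
features, and the cap equals twice the number of features whose
resultant loading exceeds the uniform share 1/199.

Additional research selectors can be registered through
:func:`register_ranker` without modifying this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

from falladl.features import (
    N_FEATURES,
    FeatureMatrix,
    SCALING_PER_DATASET,
    SCALING_RAW,
    SCALING_TRAIN_FIT,
)

RELIEFF_K = 10          # same/other-class neighbors per instance
N_BINS = 20             # equal-width bins for information-theoretic rankers


class MethodError(ValueError):
    """Ranking method cannot run on this input."""


class SelectionConfigError(ValueError):
    """Unknown method or invalid option."""


@dataclass
class RankingResult:
    """Ordered permutation of feature ids (1-based), most to least important."""

    method: str
    order: np.ndarray       # permutation of 1..F (F = 199 for full matrices)
    scores: np.ndarray      # (F,) method-specific scale, indexed by feature_id-1

    def __post_init__(self) -> None:
        f = len(self.scores)
        if sorted(self.order.tolist()) != list(range(1, f + 1)):
            raise ValueError(f"order must be a permutation of 1..{f}")

    def top_columns(self, n: int) -> np.ndarray:
        """0-based column indices of the n best features."""
        return self.order[:n] - 1


@dataclass
class PcaRankOutcome:
    """PCA resultant-component ranking with the x2 feature-count cap."""

    n_components: int
    cum_explained: float
    resultant_loading: np.ndarray   # (199,) non-negative, sums to 1
    n_above_uniform: int
    cap: int
    order: np.ndarray               # permutation of 1..199 by descending loading

    def as_ranking(self) -> RankingResult:
        return RankingResult("pca", self.order, self.resultant_loading)


# ---------------------------------------------------------------------------
# scaling

def scale_minmax(fm: FeatureMatrix, grouping: str = "per_dataset") -> FeatureMatrix:
    """Min-max scale every feature column to [0, 1].

    ``grouping="per_dataset"`` scales each source dataset separately;
    ``grouping="train_fit"`` fits one global scaler and stores its
    parameters in ``scaling_params`` so unseen data can be transformed
    with :func:`apply_minmax`. Constant columns map to 0.
    """
    if fm.scaling_state != SCALING_RAW:
        raise ValueError("feature matrix is already scaled")
    values = fm.values.copy()
    params: dict = {"grouping": grouping}
    if grouping == "per_dataset":
        for ds in np.unique(fm.dataset_ids):
            mask = fm.dataset_ids == ds
            values[mask] = _minmax(values[mask])[0]
        state = SCALING_PER_DATASET
    elif grouping == "train_fit":
        values, lo, span = _minmax(values)
        params.update(lo=lo, span=span)
        state = SCALING_TRAIN_FIT
    else:
        raise SelectionConfigError(f"unknown scaling grouping {grouping!r}")
    out = FeatureMatrix(
        values=values, labels=fm.labels, subject_ids=fm.subject_ids,
        dataset_ids=fm.dataset_ids, descriptors=fm.descriptors,
        scaling_state=state, scaling_params=params,
    )
    return out


def _minmax(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = block.min(axis=0)
    span = block.max(axis=0) - lo
    safe = np.where(span == 0, 1.0, span)
    return np.clip((block - lo) / safe, 0.0, 1.0) * (span != 0), lo, span


def apply_minmax(fm: FeatureMatrix, params: dict) -> FeatureMatrix:
    """Transform unseen data with stored train-fit min-max parameters."""
    if fm.scaling_state != SCALING_RAW:
        raise ValueError("feature matrix is already scaled")
    lo, span = params["lo"], params["span"]
    safe = np.where(span == 0, 1.0, span)
    values = np.clip((fm.values - lo) / safe, 0.0, 1.0) * (span != 0)
    return FeatureMatrix(
        values=values, labels=fm.labels, subject_ids=fm.subject_ids,
        dataset_ids=fm.dataset_ids, descriptors=fm.descriptors,
        scaling_state=SCALING_TRAIN_FIT, scaling_params=dict(params),
    )


# ---------------------------------------------------------------------------
# rankers

def _check_ranking_input(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if fm.scaling_state == SCALING_RAW:
        raise ValueError("scale the feature matrix before ranking")
    y = np.asarray(fm.labels)
    if np.unique(y).size < 2:
        raise MethodError("ranking requires at least two classes")
    return fm.values, y


def _order_from_scores(scores: np.ndarray) -> np.ndarray:
    """Descending-score order; ties broken by ascending feature id."""
    # stable sort on -scores keeps ascending index order within ties
    return np.argsort(-scores, kind="stable") + 1


def relieff_scores(X: np.ndarray, y: np.ndarray, k: int = RELIEFF_K) -> np.ndarray:
    """Relief-F feature weights, k nearest hits/misses, all instances.

    Manhattan (L1) per-feature differences on the scaled features; miss
    contributions weighted by the class prior P(c)/(1 - P(y_i)).
    Neighbor ties are resolved by ascending instance index.
    """
    X = np.asarray(X, float)
    n, f = X.shape
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes.tolist(), (counts / n).tolist()))
    span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(span == 0, 1.0, span)
    W = np.zeros(f)
    # index lists per class
    by_class = {c: np.flatnonzero(y == c) for c in classes}
    for i in range(n):
        diffs = np.abs(X - X[i]) / safe        # (n, f) normalized differences
        dist = diffs.sum(axis=1)
        for c in classes:
            idx = by_class[c]
            idx = idx[idx != i]
            if idx.size == 0:
                continue
            kk = min(k, idx.size)
            near = idx[np.argsort(dist[idx], kind="stable")[:kk]]
            contrib = diffs[near].mean(axis=0)
            if c == y[i]:
                W -= contrib
            else:
                W += priors[c] / (1.0 - priors[y[i]]) * contrib
    return W / n


def _discretize(X: np.ndarray, bins: int = N_BINS) -> np.ndarray:
    """Equal-width binning per column into integer codes 0..bins-1."""
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    safe = np.where(span == 0, 1.0, span)
    codes = np.floor((X - lo) / safe * bins).astype(int)
    return np.clip(codes, 0, bins - 1)


def _mutual_info(codes: np.ndarray, y_codes: np.ndarray) -> float:
    """MI in nats between two integer code vectors."""
    joint = np.zeros((codes.max() + 1, y_codes.max() + 1))
    np.add.at(joint, (codes, y_codes), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def mutinf_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    codes = _discretize(X)
    _, y_codes = np.unique(y, return_inverse=True)
    return np.array([_mutual_info(codes[:, j], y_codes) for j in range(X.shape[1])])


def _mrmr_order(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy mRMR (MID: relevance minus mean redundancy) ordering."""
    codes = _discretize(X)
    _, y_codes = np.unique(y, return_inverse=True)
    f = X.shape[1]
    relevance = np.array([_mutual_info(codes[:, j], y_codes) for j in range(f)])
    selected: list[int] = []
    remaining = list(range(f))
    red_sum = np.zeros(f)
    scores = np.zeros(f)
    mi_cache: dict[int, np.ndarray] = {}
    while remaining:
        if not selected:
            crit = relevance[remaining]
        else:
            crit = relevance[remaining] - red_sum[remaining] / len(selected)
        # argmax with tie-break by ascending feature index
        best = remaining[int(np.argmax(crit))]
        scores[best] = float(crit[remaining.index(best)])
        selected.append(best)
        remaining.remove(best)
        if remaining:
            mi_cache[best] = np.array(
                [_mutual_info(codes[:, best], codes[:, j]) for j in range(f)])
            red_sum += mi_cache[best]
    order = np.array(selected) + 1
    return order, scores


def _correlation_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """sqrt of the between-class variance fraction (eta)."""
    tot = x.var()
    if tot == 0:
        return 0.0
    between = 0.0
    for c in np.unique(y):
        m = y == c
        between += m.mean() * (x[m].mean() - x.mean()) ** 2
    return float(np.sqrt(between / tot))


def _cfs_order(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy forward CFS: merit = k*r_cf / sqrt(k + k(k-1)*r_ff).

    r_cf is the feature-class correlation ratio, r_ff the mean absolute
    Pearson correlation among selected features. Features are ranked by
    the order they enter the greedy selection; once no candidate
    improves the merit, the remainder is appended by descending r_cf.
    """
    f = X.shape[1]
    r_cf = np.array([_correlation_ratio(X[:, j], y) for j in range(f)])
    std = X.std(axis=0)
    safe = np.where(std == 0, 1.0, std)
    Z = (X - X.mean(axis=0)) / safe
    C = np.abs(Z.T @ Z / X.shape[0]) * np.outer(std != 0, std != 0)
    selected: list[int] = []
    scores = np.zeros(f)
    remaining = list(range(f))
    best_merit = -np.inf
    while remaining:
        merits = []
        for j in remaining:
            cand = selected + [j]
            k = len(cand)
            rcf = r_cf[cand].mean()
            if k == 1:
                rff = 0.0
            else:
                sub = C[np.ix_(cand, cand)]
                rff = (sub.sum() - k) / (k * (k - 1))
            merits.append(k * rcf / np.sqrt(k + k * (k - 1) * rff))
        i = int(np.argmax(merits))
        if merits[i] <= best_merit:
            break
        best_merit = merits[i]
        j = remaining.pop(i)
        selected.append(j)
        scores[j] = merits[i]
    # append the rest by descending class correlation, tie by feature id
    rest = sorted(remaining, key=lambda j: (-r_cf[j], j))
    order = np.array(selected + rest) + 1
    for j in rest:
        scores[j] = -1.0 + r_cf[j]  # keep below any selected merit
    return order, scores


def _lasso_order(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Rank by the order features enter the one-vs-rest L1 logistic path.

    C is swept over a decreasing-strength (increasing C) grid; a
    feature's score is the largest regularization strength (1/C) at
    which any one-vs-rest coefficient is non-zero, i.e. earlier entry ->
    higher score. Features never entering score 0; ties by feature id.
    """
    Cs = np.logspace(-3, 2, 16)
    f = X.shape[1]
    entry = np.full(f, -1, dtype=int)
    for step, C in enumerate(Cs):
        clf = OneVsRestClassifier(LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=float(C), max_iter=200,
            random_state=seed,
        ))
        clf.fit(X, y)
        coef = np.vstack([est.coef_ for est in clf.estimators_])
        active = (np.abs(coef) > 1e-8).any(axis=0)
        newly = active & (entry < 0)
        entry[newly] = step
        if (entry >= 0).all():
            break
    scores = np.where(entry < 0, 0.0, float(len(Cs)) - entry)
    return _order_from_scores(scores), scores


_BUILTIN_RANKERS: dict[str, Callable] = {}
_PLUGIN_RANKERS: dict[str, Callable] = {}


def register_ranker(name: str, fn: Callable) -> None:
    """Register a plugin ranker ``fn(fm, seed) -> RankingResult``."""
    _PLUGIN_RANKERS[name] = fn


def available_methods() -> tuple[str, ...]:
    return tuple(sorted(set(_BUILTIN_RANKERS) | set(_PLUGIN_RANKERS) | {"pca"}))


def rank(fm: FeatureMatrix, method: str, seed: int = 0) -> RankingResult:
    """Rank all features with one of the built-in or plugin methods.

    Built-in methods: ``relieff``, ``mutinf``, ``mrmr``, ``cfs``,
    ``lasso``. Deterministic given the seed; ties everywhere resolved
    by ascending feature id.
    """
    if method in _PLUGIN_RANKERS:
        return _PLUGIN_RANKERS[method](fm, seed)
    X, y = _check_ranking_input(fm)
    if method == "relieff":
        scores = relieff_scores(X, y)
        return RankingResult(method, _order_from_scores(scores), scores)
    if method == "mutinf":
        scores = mutinf_scores(X, y)
        return RankingResult(method, _order_from_scores(scores), scores)
    if method == "mrmr":
        order, scores = _mrmr_order(X, y)
        return RankingResult(method, order, scores)
    if method == "cfs":
        order, scores = _cfs_order(X, y)
        return RankingResult(method, order, scores)
    if method == "lasso":
        order, scores = _lasso_order(X, y, seed)
        return RankingResult(method, order, scores)
    raise SelectionConfigError(
        f"unknown ranking method {method!r}; available: {available_methods()}")


def pca_rank(fm: FeatureMatrix, target: float = 0.70) -> PcaRankOutcome:
    """PCA resultant-component ranking and the x2 feature-count cap.

    PCA is run on the scaled (mean-centered, not re-standardized)
    feature matrix. The smallest m with cumulative explained variance
    >= ``target`` is kept; the resultant loading of feature j is the
    normalized sum over the m components of |loading| weighted by each
    component's share of the retained explained variance. The cap is
    twice the count of features whose resultant loading strictly
    exceeds the uniform share 1/199.
    """
    if fm.scaling_state == SCALING_RAW:
        raise ValueError("scale the feature matrix before PCA ranking")
    X = fm.values
    if X.std(axis=0).max() == 0:
        raise MethodError("zero-variance feature matrix")
    if fm.n_windows <= X.shape[1]:
        import warnings

        warnings.warn(
            f"PCA on {fm.n_windows} windows <= {X.shape[1]} features; "
            "loadings may be unstable", stacklevel=2)
    n_max = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, target) + 1)
    m = min(m, n_max)
    ev = pca.explained_variance_ratio_[:m]
    weights = ev / ev.sum()
    resultant = (weights[:, None] * np.abs(pca.components_[:m])).sum(axis=0)
    resultant = resultant / resultant.sum()
    # strictly above the uniform level; small tolerance so rounding noise
    # cannot promote an exactly-uniform loading past the threshold
    uniform = 1.0 / X.shape[1]
    n_above = int(np.count_nonzero(resultant > uniform * (1.0 + 1e-9)))
    return PcaRankOutcome(
        n_components=m,
        cum_explained=float(cum[m - 1]),
        resultant_loading=resultant,
        n_above_uniform=n_above,
        cap=2 * n_above,
        order=_order_from_scores(resultant),
    )
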
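"""Nested cross-validated treatment-response classification.

The training pipeline for every fold is: mRMR feature ranking (top 50 by
the mutual-information difference criterion) -> SMOTE minority
over-sampling to exact class parity -> sequential forward selection (at
most 10 features, greedy on inner-CV accuracy of the chosen classifier) ->
hyperparameter tuning (KNN k in {1, 3, 5}; SVM-RBF C in 2^8..2^15, gamma
in 2^-18..2^-5) -> final fit.  The held-out data of the outer fold never
participates in standardization, selection, balancing or tuning.

The positive class is the non-responder (NR): clinically, the model's PPV
is the chance of correctly flagging a patient who will not respond to
neoadjuvant chemotherapy.

Inner loops score KNN via precomputed per-feature squared-distance matrices
(distances are additive across features, so forward selection is
incremental) and SVM via precomputed RBF Gram matrices handed to
scikit-learn's SVC; final models are ordinary scikit-learn estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import config_context
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

try:  # compiled kernels for the inner-CV loops
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap

__all__ = [
    "ClassifierSpec",
    "SelectionSpec",
    "CVResult",
    "MetricBlock",
    "screen_features",
    "mrmr_select",
    "smote_balance",
    "smote_augment",
    "sfs_select",
    "fit_predict",
    "train_pipeline",
    "PipelineModel",
    "nested_loo_cv",
    "loo_cv_with_global_selection",
    "holdout_cv",
    "compute_metrics",
    "pooled_group_mean",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "NR"


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family and its hyperparameter grids."""

    kind: str = "KNN"  # "KNN" | "SVM-RBF"
    knn_k_grid: tuple = (1, 3, 5)
    svm_c_grid: tuple = tuple(2.0**p for p in range(8, 16))
    svm_gamma_grid: tuple = tuple(2.0**p for p in range(-18, -4))
    positive_class: str = POSITIVE_CLASS

    def __post_init__(self) -> None:
        if self.kind not in ("KNN", "SVM-RBF"):
            raise ValueError("kind must be 'KNN' or 'SVM-RBF'")
        if not self.knn_k_grid or not self.svm_c_grid or not self.svm_gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(k % 2 == 0 for k in self.knn_k_grid):
            raise ValueError("KNN k must be odd (binary vote cannot tie)")


@dataclass(frozen=True)
class SelectionSpec:
    """Feature-selection and balancing configuration."""

    mrmr_top: int = 50
    sfs_max: int = 10
    smote_neighbors: int = 5
    mi_bins: int = 4
    inner_folds: int = 2
    #: score SFS/tuning on a single stratified train/validation split
    #: (the first fold) instead of full k-fold rotation
    inner_single_split: bool = True

    def __post_init__(self) -> None:
        if self.sfs_max > self.mrmr_top:
            raise ValueError("sfs_max must not exceed mrmr_top")


@dataclass
class MetricBlock:
    """Sensitivity/specificity/accuracy/PPV/NPV in percent, AUC in [0, 1]."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold predictions plus pooled metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    metrics: MetricBlock
    selected_features: list = field(default_factory=list)
    train_metrics_mean: dict | None = None
    train_metrics_sd: dict | None = None
    test_metrics_mean: dict | None = None
    test_metrics_sd: dict | None = None
    bias_error: float | None = None
    variance_error: float | None = None


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def screen_features(X: np.ndarray, y: Sequence, positive: str = POSITIVE_CLASS) -> np.ndarray:
    """Two-sided unpaired (Student) t-test p-value per feature.

    Constant features are flagged NaN.  Requires >= 2 samples per class.
    """
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    if (yb == 1).sum() < 2 or (yb == 0).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    a, b = X[yb == 1], X[yb == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(a, b, axis=0, equal_var=True).pvalue
    const = X.std(axis=0) == 0
    p = np.where(const, np.nan, p)
    return p


# ---------------------------------------------------------------------------
# mRMR (mutual-information difference criterion)
# ---------------------------------------------------------------------------


def _as_binary(y: Sequence, positive: str = POSITIVE_CLASS) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "biu" and set(np.unique(arr)) <= {0, 1}:
        return arr.astype(np.int64)
    return (arr == positive).astype(np.int64)


def _quantile_discretize(X: np.ndarray, bins: int) -> np.ndarray:
    """Per-feature quantile binning into ``bins`` levels (0..bins-1)."""
    X = np.asarray(X, dtype=float)
    qs = np.quantile(X, np.linspace(0, 1, bins + 1)[1:-1], axis=0)
    out = np.zeros(X.shape, dtype=np.int64)
    for cut in qs:
        out += X > cut[None, :]
    return out


def _mi_features_vs(codes: np.ndarray, target: np.ndarray, n_code: int, n_target: int) -> np.ndarray:
    """MI (nats) between every column of ``codes`` and ``target``."""
    n, f = codes.shape
    joint_idx = (codes * n_target + target[:, None]) + np.arange(f)[None, :] * (n_code * n_target)
    counts = np.bincount(joint_idx.ravel(), minlength=f * n_code * n_target).reshape(
        f, n_code, n_target
    )
    pxy = counts / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = pxy * np.log(pxy / (px * py))
    return np.nansum(t, axis=(1, 2))


@_njit(cache=False)
def _mi_features_vs_fast(codesT, target, n_code, n_target):
    """Compiled MI of every (row-major) feature of ``codesT`` with ``target``."""
    f, n = codesT.shape
    out = np.empty(f)
    cnt = np.zeros((n_code, n_target))
    for j in range(f):
        cnt[:] = 0.0
        for i in range(n):
            cnt[codesT[j, i], target[i]] += 1.0
        mi = 0.0
        for a in range(n_code):
            pa = 0.0
            for b in range(n_target):
                pa += cnt[a, b]
            if pa == 0.0:
                continue
            for b in range(n_target):
                pab = cnt[a, b]
                if pab == 0.0:
                    continue
                pb = 0.0
                for a2 in range(n_code):
                    pb += cnt[a2, b]
                mi += (pab / n) * np.log(pab * n / (pa * pb))
        out[j] = mi
    return out


def mrmr_select(
    X: np.ndarray,
    y: Sequence,
    top: int = 50,
    bins: int = 4,
    positive: str = POSITIVE_CLASS,
) -> list[int]:
    """Greedy maximal-relevance-minimal-redundancy feature ranking.

    The first feature maximizes mutual information with the label; each
    subsequent pick maximizes relevance minus mean redundancy with the
    already-selected set (the MID criterion).  MI is estimated on
    quantile-discretized features.  Returns column indices in selection
    order (all columns, ordered, when fewer than ``top`` exist).
    """
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    if np.unique(yb).size < 2:
        raise ValueError("labels are degenerate (single class)")
    if top <= 0:
        return []
    n, f = X.shape
    top = min(top, f)
    codes = _quantile_discretize(X, bins)
    codesT = np.ascontiguousarray(codes.T)
    if _HAVE_NUMBA:
        mi_all = lambda target, n_t: _mi_features_vs_fast(codesT, target, bins, n_t)
    else:  # pragma: no cover - numba is a declared dependency
        mi_all = lambda target, n_t: _mi_features_vs(codes, target, bins, n_t)
    relevance = mi_all(yb, 2)
    selected = [int(np.argmax(relevance))]
    red_sum = np.zeros(f)
    remaining = np.ones(f, dtype=bool)
    remaining[selected[0]] = False
    while len(selected) < top:
        red_sum += mi_all(codesT[selected[-1]], bins)
        score = relevance - red_sum / len(selected)
        score[~remaining] = -np.inf
        nxt = int(np.argmax(score))
        selected.append(nxt)
        remaining[nxt] = False
    return selected


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_balance(
    minority: np.ndarray,
    n_new: int,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic minority rows: ``x + u (x_nn - x)`` with u ~ U(0,1).

    Each synthetic row interpolates a minority row towards one of its ``k``
    nearest minority neighbours (Euclidean).
    """
    minority = np.asarray(minority, dtype=float)
    if minority.shape[0] < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    rng = rng or np.random.default_rng()
    if n_new <= 0:
        return np.empty((0, minority.shape[1]))
    d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    k_eff = min(k, minority.shape[0] - 1)
    nn = np.argsort(d2, axis=1)[:, :k_eff]
    base = rng.integers(0, minority.shape[0], n_new)
    pick = nn[base, rng.integers(0, k_eff, n_new)]
    u = rng.uniform(size=(n_new, 1))
    return minority[base] + u * (minority[pick] - minority[base])


def smote_augment(
    X: np.ndarray,
    y: Sequence,
    k: int = 5,
    rng: np.random.Generator | None = None,
    positive: str = POSITIVE_CLASS,
) -> tuple[np.ndarray, np.ndarray]:
    """Append synthetic minority rows until the classes are exactly equal.

    Original rows are returned unmodified, synthetic rows appended at the
    end with the minority label.
    """
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    n1, n0 = int((yb == 1).sum()), int((yb == 0).sum())
    if n1 == n0:
        return X.copy(), yb.copy()
    min_label = 1 if n1 < n0 else 0
    n_new = abs(n0 - n1)
    synth = smote_balance(X[yb == min_label], n_new, k=k, rng=rng)
    return np.vstack([X, synth]), np.concatenate([yb, np.full(n_new, min_label, dtype=np.int64)])


# ---------------------------------------------------------------------------
# Inner-CV machinery
# ---------------------------------------------------------------------------


def _stratified_folds(yb: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random stratified fold assignment (list of test-index arrays)."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for label in (0, 1):
        idx = np.flatnonzero(yb == label)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


@_njit(cache=False)
def _build_sqdiff(X):
    """Per-feature pairwise squared differences: (f, n, n), float32."""
    n, f = X.shape
    D = np.empty((f, n, n), dtype=np.float32)
    for j in range(f):
        for a in range(n):
            xa = X[a, j]
            for b in range(n):
                d = xa - X[b, j]
                D[j, a, b] = d * d
    return D


@_njit(cache=False)
def _knn_correct_many(Df, d_sel, y, te_start, te_end, cands, k):
    """Correct-count per candidate feature added to the selected set.

    Rows are pre-permuted so the test fold is the contiguous range
    ``[te_start, te_end)`` and the training rows its complement; for every
    candidate j the KNN vote for each test row uses distances
    ``d_sel + Df[j]`` (fused top-k scan, no intermediate matrix).  When the
    test range covers all rows the scoring is leave-one-out: each row is
    classified by its neighbours among the remaining rows.
    """
    n = d_sel.shape[0]
    nc = cands.shape[0]
    loo = (te_end - te_start) == n
    ntr = n - 1 if loo else n - (te_end - te_start)
    kk = k if k < ntr else ntr
    correct = np.zeros(nc, dtype=np.int64)
    bd = np.empty(kk, dtype=np.float32)
    by = np.empty(kk, dtype=np.int64)
    for ci in range(nc):
        j = cands[ci]
        for it in range(te_start, te_end):
            cnt = 0
            wi = 0
            base = d_sel[it]
            if j >= 0:
                feat = Df[j, it]
            else:
                feat = base  # unused sentinel; avoids an Optional type
            # training rows: the two contiguous ranges around the test fold
            # (around the row itself in leave-one-out mode)
            if loo:
                tr_ranges = ((0, it), (it + 1, n))
            else:
                tr_ranges = ((0, te_start), (te_end, n))
            for lo, hi in tr_ranges:
                for ir in range(lo, hi):
                    d = base[ir] + feat[ir] if j >= 0 else base[ir]
                    if cnt < kk:
                        bd[cnt] = d
                        by[cnt] = y[ir]
                        cnt += 1
                        if cnt == kk:
                            wi = 0
                            for q in range(1, kk):
                                if bd[q] > bd[wi]:
                                    wi = q
                    elif d < bd[wi]:
                        bd[wi] = d
                        by[wi] = y[ir]
                        wi = 0
                        for q in range(1, kk):
                            if bd[q] > bd[wi]:
                                wi = q
            votes = 0
            for q in range(cnt):
                votes += by[q]
            pred = 1 if votes * 2 > cnt else 0
            if pred == y[it]:
                correct[ci] += 1
    return correct


@_njit(cache=False)
def _knn_loo_scores_many(Df, d_sel, y, cands, k):
    """Leave-one-out positive-vote fraction per (candidate, row).

    For every candidate feature j and every row, the fraction of positive
    labels among the k nearest neighbours (excluding the row itself) under
    distances ``d_sel + Df[j]``.
    """
    n = d_sel.shape[0]
    nc = cands.shape[0]
    kk = k if k < n - 1 else n - 1
    out = np.empty((nc, n))
    bd = np.empty(kk, dtype=np.float32)
    by = np.empty(kk, dtype=np.int64)
    for ci in range(nc):
        j = cands[ci]
        for it in range(n):
            cnt = 0
            wi = 0
            base = d_sel[it]
            if j >= 0:
                feat = Df[j, it]
            else:
                feat = base
            for lo, hi in ((0, it), (it + 1, n)):
                for ir in range(lo, hi):
                    d = base[ir] + feat[ir] if j >= 0 else base[ir]
                    if cnt < kk:
                        bd[cnt] = d
                        by[cnt] = y[ir]
                        cnt += 1
                        if cnt == kk:
                            wi = 0
                            for q in range(1, kk):
                                if bd[q] > bd[wi]:
                                    wi = q
                    elif d < bd[wi]:
                        bd[wi] = d
                        by[wi] = y[ir]
                        wi = 0
                        for q in range(1, kk):
                            if bd[q] > bd[wi]:
                                wi = q
            votes = 0
            for q in range(cnt):
                votes += by[q]
            out[ci, it] = votes / cnt
    return out


class _InnerScorer:
    """Inner-CV accuracy with incremental feature subsets.

    Rows are permuted once so each stratified fold occupies a contiguous
    index range.  Squared Euclidean distances are additive over features,
    so the distance (and RBF Gram) matrix of a candidate subset S u {j} is
    obtained from S's matrix plus feature j's precomputed pairwise matrix.
    KNN votes run in a compiled kernel; SVM candidates go through
    scikit-learn's SVC on precomputed Gram matrices.
    """

    def __init__(
        self,
        X: np.ndarray,
        yb: np.ndarray,
        n_folds: int,
        rng: np.random.Generator,
        single_split: bool = False,
    ):
        yb = np.asarray(yb, dtype=np.int64)
        test_folds = _stratified_folds(yb, n_folds, rng)
        perm = np.concatenate([f for f in test_folds if f.size])
        bounds = np.cumsum([0] + [f.size for f in test_folds if f.size])
        self.ranges = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]
        if single_split and len(self.ranges) > 1:
            self.ranges = self.ranges[:1]
        self.X32 = np.ascontiguousarray(np.asarray(X, dtype=np.float32)[perm])
        self.yb = np.ascontiguousarray(yb[perm])
        n = self.X32.shape[0]
        self.Df = _build_sqdiff(self.X32)  # (f, n, n)
        self.d_sel = np.zeros((n, n), dtype=np.float32)
        self._n_eval = sum(te - ts for ts, te in self.ranges)

    def add_feature(self, j: int) -> None:
        self.d_sel += self.Df[j]

    # -- KNN ---------------------------------------------------------------
    def knn_accuracy_many(self, cands: np.ndarray, k: int) -> np.ndarray:
        """Accuracy of S u {j} for every candidate j (compiled scan)."""
        correct = np.zeros(cands.size, dtype=np.int64)
        cands64 = np.ascontiguousarray(cands, dtype=np.int64)
        for ts, te in self.ranges:
            correct += _knn_correct_many(self.Df, self.d_sel, self.yb, ts, te, cands64, k)
        return correct / self._n_eval

    def knn_accuracy(self, k: int) -> float:
        """Accuracy of the current selected set (no candidate)."""
        none = np.array([-1], dtype=np.int64)
        correct = 0
        for ts, te in self.ranges:
            correct += int(_knn_correct_many(self.Df, self.d_sel, self.yb, ts, te, none, k)[0])
        return correct / self._n_eval

    # -- SVM ---------------------------------------------------------------
    def svm_accuracy(self, d: np.ndarray, c: float, gamma: float) -> float:
        K = np.exp(-gamma * d.astype(np.float64))
        correct = 0
        n = self.yb.size
        # skip sklearn's per-fit validation: the Gram matrices are built
        # in-process and finite by construction
        with config_context(skip_parameter_validation=True, assume_finite=True):
            for ts, te in self.ranges:
                tr = np.concatenate([np.arange(0, ts), np.arange(te, n)])
                clf = SVC(C=c, kernel="precomputed")
                clf.fit(K[np.ix_(tr, tr)], self.yb[tr])
                pred = clf.predict(K[ts:te][:, tr])
                correct += int((pred == self.yb[ts:te]).sum())
        return correct / self._n_eval


def sfs_select(
    X: np.ndarray,
    y: Sequence,
    clf_spec: ClassifierSpec,
    max_features: int = 10,
    inner_folds: int = 2,
    rng: np.random.Generator | None = None,
    positive: str = POSITIVE_CLASS,
    single_split: bool = True,
) -> list[int]:
    """Sequential forward selection maximizing inner-validation accuracy.

    Candidates are tried in column order (ties keep the earlier candidate);
    selection stops at ``max_features`` or when no addition strictly
    improves the inner accuracy.  During selection the classifier runs with
    fixed default hyperparameters (KNN k=3, the grid median; SVM C=1,
    gamma=1/n_features); the full grids are searched during tuning, after
    selection.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("no candidate features")
    if max_features <= 0:
        return []
    yb = _as_binary(y, positive)
    rng = rng or np.random.default_rng()
    scorer = _InnerScorer(X, yb, inner_folds, rng, single_split=single_split)
    selected: list[int] = []
    best = -np.inf
    remaining = list(range(X.shape[1]))
    while remaining and len(selected) < max_features:
        cands = np.array(remaining)
        if clf_spec.kind == "KNN":
            accs = scorer.knn_accuracy_many(cands, k=3)
        else:
            dim = len(selected) + 1
            accs = np.array(
                [
                    scorer.svm_accuracy(scorer.d_sel + scorer.Df[j], c=1.0, gamma=1.0 / dim)
                    for j in cands
                ]
            )
        i_best = int(np.argmax(accs))
        if accs[i_best] <= best:
            break
        best = float(accs[i_best])
        j = int(cands[i_best])
        selected.append(j)
        scorer.add_feature(j)
        remaining.remove(j)
        if best >= 1.0:
            break
    return selected


def _tune(
    X: np.ndarray,
    yb: np.ndarray,
    clf_spec: ClassifierSpec,
    inner_folds: int,
    rng: np.random.Generator,
    single_split: bool = True,
) -> dict:
    """Grid-search hyperparameters by inner-validation accuracy (ties: grid order)."""
    scorer = _InnerScorer(X, yb, inner_folds, rng, single_split=single_split)
    d = scorer.Df.sum(axis=0)
    scorer.d_sel = d
    if clf_spec.kind == "KNN":
        best_k, best_acc = clf_spec.knn_k_grid[0], -np.inf
        for k in clf_spec.knn_k_grid:
            acc = scorer.knn_accuracy(k)
            if acc > best_acc:
                best_k, best_acc = k, acc
        return {"k": best_k}
    best, best_acc = None, -np.inf
    for gamma in clf_spec.svm_gamma_grid:
        for c in clf_spec.svm_c_grid:
            acc = scorer.svm_accuracy(d, c, gamma)
            if acc > best_acc:
                best, best_acc = {"C": c, "gamma": gamma}, acc
    return best


def _make_estimator(clf_spec: ClassifierSpec, params: dict):
    if clf_spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=params["k"])
    return SVC(C=params["C"], gamma=params["gamma"], kernel="rbf")


def fit_predict(
    clf_spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    inner_folds: int = 2,
    rng: np.random.Generator | None = None,
    positive: str = POSITIVE_CLASS,
) -> tuple[np.ndarray, np.ndarray]:
    """Tune on inner folds, fit, and score the test rows.

    Features must already be standardized on training statistics.  Returns
    (binary predictions, continuous scores): the fraction of positive
    neighbours for KNN, the signed decision value for SVM.
    """
    yb = _as_binary(y_train, positive)
    if np.unique(yb).size < 2:
        raise ValueError("training set must contain both classes")
    rng = rng or np.random.default_rng()
    params = _tune(np.asarray(X_train, float), yb, clf_spec, inner_folds, rng)
    est = _make_estimator(clf_spec, params)
    est.fit(X_train, yb)
    if clf_spec.kind == "KNN":
        scores = est.predict_proba(X_test)[:, list(est.classes_).index(1)]
    else:
        scores = est.decision_function(X_test)
    pred = est.predict(X_test)
    return pred.astype(np.int64), np.asarray(scores, dtype=float)


# ---------------------------------------------------------------------------
# Training pipeline and outer CV
# ---------------------------------------------------------------------------


@dataclass
class PipelineModel:
    """A trained fold model: scaler stats, selected columns, estimator."""

    mean: np.ndarray
    scale: np.ndarray
    mrmr_columns: list
    selected_columns: list
    params: dict
    estimator: object
    clf_spec: ClassifierSpec

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xs = (np.asarray(X, float) - self.mean) / self.scale
        Xs = Xs[:, self.selected_columns]
        est = self.estimator
        pred = est.predict(Xs).astype(np.int64)
        if self.clf_spec.kind == "KNN":
            scores = est.predict_proba(Xs)[:, list(est.classes_).index(1)]
        else:
            scores = est.decision_function(Xs)
        return pred, np.asarray(scores, dtype=float)


def train_pipeline(
    X: np.ndarray,
    y: Sequence,
    clf_spec: ClassifierSpec,
    sel_spec: SelectionSpec,
    rng: np.random.Generator,
    positive: str = POSITIVE_CLASS,
) -> PipelineModel:
    """mRMR -> SMOTE -> SFS -> tune -> fit, on training rows only."""
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    Xs = np.nan_to_num(Xs, nan=0.0)

    ranked = mrmr_select(Xs, yb, top=sel_spec.mrmr_top, bins=sel_spec.mi_bins)
    Xr = Xs[:, ranked]
    Xb, yb_bal = smote_augment(Xr, yb, k=sel_spec.smote_neighbors, rng=rng)
    local_sel = sfs_select(
        Xb, yb_bal, clf_spec, max_features=sel_spec.sfs_max,
        inner_folds=sel_spec.inner_folds, rng=rng,
        single_split=sel_spec.inner_single_split,
    )
    if not local_sel:
        local_sel = [0]
    selected = [ranked[i] for i in local_sel]
    params = _tune(Xb[:, local_sel], yb_bal, clf_spec, sel_spec.inner_folds, rng,
                   single_split=sel_spec.inner_single_split)
    est = _make_estimator(clf_spec, params)
    est.fit(Xb[:, local_sel], yb_bal)
    return PipelineModel(
        mean=mean, scale=scale, mrmr_columns=ranked, selected_columns=selected,
        params=params, estimator=est, clf_spec=clf_spec,
    )


def nested_loo_cv(
    X: np.ndarray,
    y: Sequence,
    clf_spec: ClassifierSpec,
    sel_spec: SelectionSpec | None = None,
    seed: int = 0,
    feature_names: Sequence | None = None,
    positive: str = POSITIVE_CLASS,
) -> CVResult:
    """Nested leave-one-out cross-validation.

    For each of the n outer folds the complete training pipeline runs on
    the n-1 remaining rows; the held-out row is only ever scored.  The n
    held-out predictions are pooled into one confusion matrix and ROC.
    """
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    sel_spec = sel_spec or SelectionSpec()
    preds = np.zeros(n, dtype=np.int64)
    scores = np.zeros(n)
    selected_all = []
    root = np.random.default_rng(seed)
    fold_seeds = root.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        model = train_pipeline(
            X[tr], yb[tr], clf_spec, sel_spec, np.random.default_rng(fold_seeds[i])
        )
        p, s = model.predict(X[i : i + 1])
        preds[i] = p[0]
        scores[i] = s[0]
        if feature_names is not None:
            selected_all.append([feature_names[j] for j in model.selected_columns])
        else:
            selected_all.append(list(model.selected_columns))
    metrics = compute_metrics(yb, preds, scores)
    return CVResult(y_true=yb, y_pred=preds, scores=scores, metrics=metrics,
                    selected_features=selected_all)


def loo_cv_with_global_selection(
    X: np.ndarray,
    y: Sequence,
    clf_spec: ClassifierSpec,
    sel_spec: SelectionSpec | None = None,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> CVResult:
    """Deliberately *leaky* LOO: selection/tuning on ALL rows, then LOO refits.

    This is a diagnostic for information leakage, wrong by design: the
    forward selection and the k grid search greedily maximize leave-one-out
    accuracy computed over *every* row (after SMOTE balancing of the full
    data), so the feature subset is optimized against the very rows later
    reported as held out.  On label-independent data this inflates the
    apparent AUC well above chance.  KNN only; never use it to report
    performance.
    """
    if clf_spec.kind != "KNN":
        raise ValueError("the leakage diagnostic is defined for the KNN pipeline")
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    sel_spec = sel_spec or SelectionSpec()
    rng = np.random.default_rng(seed)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = np.nan_to_num((X - mean) / scale, nan=0.0)
    ranked = mrmr_select(Xs, yb, top=sel_spec.mrmr_top, bins=sel_spec.mi_bins)
    Xr = Xs[:, ranked]
    # greedy forward selection maximizing the pooled LOO AUC over *all*
    # rows -- the exact statistic reported afterwards (the leak)
    scorer = _InnerScorer(Xr, yb, 1, rng)
    yb_perm = scorer.yb  # scorer permutes rows; AUC is permutation-invariant
    n_pos = int(yb_perm.sum())
    n_neg = yb_perm.size - n_pos

    def pooled_auc(score_rows: np.ndarray) -> np.ndarray:
        order = np.argsort(score_rows, axis=1, kind="stable")
        ranks = np.empty_like(order, dtype=np.float64)
        rows = np.arange(score_rows.shape[0])[:, None]
        ranks[rows, order] = np.arange(1, score_rows.shape[1] + 1)
        # midrank correction for ties via averaging of sorted duplicates
        for r in range(score_rows.shape[0]):
            s = score_rows[r]
            uniq, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
            cum = np.cumsum(counts)
            mid = cum - (counts - 1) / 2.0
            ranks[r] = mid[inv]
        pos_rank_sum = (ranks * yb_perm[None, :]).sum(axis=1)
        return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    selected: list[int] = []
    best_auc = -np.inf
    best_prefix: list[int] = []
    remaining = list(range(Xr.shape[1]))
    while remaining and len(selected) < sel_spec.sfs_max:
        cands = np.array(remaining, dtype=np.int64)
        votes = _knn_loo_scores_many(scorer.Df, scorer.d_sel, yb_perm, cands, 5)
        aucs = pooled_auc(votes)
        i_best = int(np.argmax(aucs))
        j = int(cands[i_best])
        selected.append(j)
        scorer.add_feature(j)
        remaining.remove(j)
        if aucs[i_best] > best_auc:
            best_auc = float(aucs[i_best])
            best_prefix = list(selected)
    cols = [ranked[i] for i in (best_prefix or selected[:1])]
    Xsel = Xs[:, cols]
    n = X.shape[0]
    preds = np.zeros(n, dtype=np.int64)
    scores = np.zeros(n)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        est = _make_estimator(clf_spec, {"k": 5})
        est.fit(Xsel[tr], yb[tr])
        scores[i] = est.predict_proba(Xsel[i : i + 1])[:, list(est.classes_).index(1)][0]
        preds[i] = est.predict(Xsel[i : i + 1])[0]
    return CVResult(y_true=yb, y_pred=preds, scores=scores,
                    metrics=compute_metrics(yb, preds, scores),
                    selected_features=[cols])


def _stratified_split(yb: np.ndarray, test_fraction: float, rng: np.random.Generator):
    te = []
    for label in (0, 1):
        idx = np.flatnonzero(yb == label)
        rng.shuffle(idx)
        n_te = int(round(test_fraction * idx.size))
        te.extend(idx[:n_te].tolist())
    te = np.sort(np.array(te, dtype=np.int64))
    tr = np.setdiff1d(np.arange(yb.size), te)
    return tr, te


def holdout_cv(
    X: np.ndarray,
    y: Sequence,
    clf_spec: ClassifierSpec,
    sel_spec: SelectionSpec | None = None,
    test_fraction: float = 0.2,
    repeats: int = 10,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> CVResult:
    """Repeated stratified hold-out validation.

    ``repeats`` random stratified splits; the full training pipeline runs
    per split and is evaluated on both partitions.  ``bias_error`` is
    100 % minus the mean test accuracy and ``variance_error`` the standard
    deviation of test accuracy across repeats (decided definitions).
    """
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y, positive)
    sel_spec = sel_spec or SelectionSpec()
    root = np.random.default_rng(seed)
    tr_blocks, te_blocks = [], []
    all_true, all_pred, all_scores = [], [], []
    for _ in range(repeats):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        tr, te = _stratified_split(yb, test_fraction, rng)
        if min(np.bincount(yb[te], minlength=2)) < 2 or np.unique(yb[tr]).size < 2:
            raise ValueError("split leaves fewer than 2 test rows in a class")
        model = train_pipeline(X[tr], yb[tr], clf_spec, sel_spec, rng)
        p_tr, s_tr = model.predict(X[tr])
        p_te, s_te = model.predict(X[te])
        tr_blocks.append(compute_metrics(yb[tr], p_tr, s_tr).as_dict())
        te_blocks.append(compute_metrics(yb[te], p_te, s_te).as_dict())
        all_true.append(yb[te])
        all_pred.append(p_te)
        all_scores.append(s_te)
    keys = ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc")
    agg = lambda blocks, f: {k: float(f([b[k] for b in blocks])) for k in keys}
    te_mean = agg(te_blocks, np.nanmean)
    pooled = compute_metrics(
        np.concatenate(all_true), np.concatenate(all_pred), np.concatenate(all_scores)
    )
    return CVResult(
        y_true=np.concatenate(all_true),
        y_pred=np.concatenate(all_pred),
        scores=np.concatenate(all_scores),
        metrics=pooled,
        train_metrics_mean=agg(tr_blocks, np.nanmean),
        train_metrics_sd=agg(tr_blocks, np.nanstd),
        test_metrics_mean=te_mean,
        test_metrics_sd=agg(te_blocks, np.nanstd),
        bias_error=100.0 - te_mean["accuracy"],
        variance_error=float(np.nanstd([b["accuracy"] for b in te_blocks])),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, scores: Sequence | None = None,
    positive: str = POSITIVE_CLASS,
) -> MetricBlock:
    """Confusion-matrix rates (percent) and trapezoidal ROC AUC.

    The positive class is the non-responder.  Zero-denominator rates are
    flagged NaN.
    """
    yt = _as_binary(y_true, positive)
    yp = _as_binary(y_pred, positive)
    tp = int(((yt == 1) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    rate = lambda a, b: float("nan") if (a + b) == 0 else 100.0 * a / (a + b)
    if scores is None or np.unique(yt).size < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(yt, np.asarray(scores, dtype=float)))
    return MetricBlock(
        sensitivity=rate(tp, fn),
        specificity=rate(tn, fp),
        accuracy=rate(tp + tn, fp + fn),
        ppv=rate(tp, fp),
        npv=rate(tn, fn),
        auc=auc,
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def pooled_group_mean(
    group_means: Sequence[float], group_sizes: Sequence[int], ndigits: int | None = None
) -> float:
    """Size-weighted mean of subgroup means (cohort-table consistency check)."""
    m = np.asarray(group_means, dtype=float)
    s = np.asarray(group_sizes, dtype=float)
    if m.shape != s.shape or m.size == 0:
        raise ValueError("means and sizes must be equal-length and non-empty")
    if np.any(s <= 0):
        raise ValueError("sizes must be positive")
    out = float(np.sum(m * s) / np.sum(s))
    return round(out, ndigits) if ndigits is not None else out
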
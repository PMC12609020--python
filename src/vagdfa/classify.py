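"""Feature-path classification: NCA weighting, RBF-SVM, stratified CV.

Feature selection uses the feature-weighting form of Neighborhood Component
Analysis: each feature k carries a weight w_k, distances are the weighted L1
metric d_ij = sum_k w_k^2 |x_ik - x_jk|, and the leave-one-out soft-nearest-
neighbor accuracy sum_i p_i (p_i = probability that a stochastic nearest
neighbour of i shares its class) is maximised with an L2 penalty on the
weights.  Normalized weights below 0.05 mark redundant or noisy features.

The classifier is a support vector machine with an RBF kernel evaluated by
stratified k-fold cross-validation; per-fold standardization prevents
train/test leakage.  The metric panel (accuracy, sensitivity, specificity,
precision, F1, AUC) is computed from the fold confusion matrices and the
continuous SVM decision values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "NcaResult",
    "CvReport",
    "nca_weights",
    "select_by_weight",
    "metrics_from_confusion",
    "roc_auc",
    "svm_rbf_cv",
]


@dataclass(frozen=True)
class NcaResult:
    weights: np.ndarray  # normalized to sum 1
    raw_weights: np.ndarray
    kept: tuple[int, ...]
    lam: float
    iterations: int
    objective: float


@dataclass
class CvReport:
    """Per-fold metrics, confusion counts and pooled ROC for one CV run."""

    folds: pd.DataFrame
    confusions: list[tuple[int, int, int, int]]  # (tp, fn, tn, fp) per fold
    roc_points: np.ndarray  # pooled (fpr, tpr) pairs
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        metric_cols = [c for c in self.folds.columns if c != "fold"]
        self.mean = {c: float(self.folds[c].mean()) for c in metric_cols}
        self.sd = {c: float(self.folds[c].std(ddof=1)) for c in metric_cols}


# ---------------------------------------------------------------------------
# Neighborhood Component Analysis (feature-weighting form)
# ---------------------------------------------------------------------------


def _nca_objective_grad(
    w: np.ndarray, absdiff: np.ndarray, same: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """LOO objective and gradient.

    ``absdiff[i, j, k] = |x_ik - x_jk|``; ``same[i, j]`` marks same-class
    pairs.  Diagonal pairs are excluded from the softmax.
    """
    n = absdiff.shape[0]
    d = absdiff @ (w**2)  # (n, n) weighted L1 distances
    np.fill_diagonal(d, np.inf)
    d -= d.min(axis=1, keepdims=True)  # softmax stabilisation
    k = np.exp(-d)
    p = k / k.sum(axis=1, keepdims=True)
    p_i = (p * same).sum(axis=1)
    obj = float(p_i.sum() - lam * float(w @ w))
    # grad_k = 2 w_k [ sum_i ( p_i sum_j p_ij A_ijk - sum_{j in class i} p_ij A_ijk ) ] - 2 lam w_k
    weighted_all = np.einsum("ij,ijk->k", p * p_i[:, None], absdiff)
    weighted_same = np.einsum("ij,ijk->k", p * same, absdiff)
    grad = 2 * w * (weighted_all - weighted_same) - 2 * lam * w
    return obj, grad


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> NcaResult:
    """Estimate per-feature NCA weights by gradient ascent.

    Features are standardized internally; weights start at 1, the step size
    halves whenever a step would decrease the objective, and the reported
    weights are |w| normalized to sum 1 (so a flat profile over p features
    sits at 1/p, e.g. 0.083 for 12 features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    if lam is None:
        lam = 1.0 / n
    Xs = StandardScaler().fit_transform(X)
    absdiff = np.abs(Xs[:, None, :] - Xs[None, :, :])
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    w = np.ones(p)
    step = 0.1
    obj, grad = _nca_objective_grad(w, absdiff, same, lam)
    iters = 0
    for iters in range(1, max_iter + 1):
        w_new = w + step * grad
        obj_new, grad_new = _nca_objective_grad(w_new, absdiff, same, lam)
        if obj_new > obj:
            if obj_new - obj < tol * max(abs(obj), 1.0):
                w, obj = w_new, obj_new
                break
            w, obj, grad = w_new, obj_new, grad_new
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-12:
                break
    raw = np.abs(w)
    total = raw.sum()
    normalized = raw / total if total > 0 else np.full(p, 1.0 / p)
    kept = tuple(int(i) for i in np.where(normalized >= 0.05)[0])
    return NcaResult(
        weights=normalized, raw_weights=raw, kept=kept, lam=lam, iterations=iters,
        objective=obj,
    )


def select_by_weight(result: NcaResult, threshold: float = 0.05) -> tuple[int, ...]:
    """Indices with normalized weight >= threshold; top-3 fallback if empty."""
    idx = np.where(result.weights >= threshold)[0]
    if idx.size == 0:
        import warnings

        warnings.warn("no feature reached the weight threshold; keeping top 3")
        idx = np.argsort(result.weights)[::-1][:3]
        idx = np.sort(idx)
    return tuple(int(i) for i in idx)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Panel of accuracy/sensitivity/specificity/precision/recall/F1.

    Ratios with zero denominators are reported as NaN.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("negative counts")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "precision": prec,
        "recall": sens,
        "f1": f1,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC over the empirical ROC curve, plus its (fpr, tpr) points.

    Ties in the scores are grouped (one ROC vertex per distinct score), which
    makes the trapezoidal area equal the rank/concordance estimator with ties
    counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    lab = labels[order]
    # cut after each run of tied scores
    distinct = np.r_[np.where(np.diff(s) != 0)[0], s.size - 1]
    tp = np.cumsum(lab)[distinct]
    fp = np.cumsum(~lab)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# SVM cross-validation
# ---------------------------------------------------------------------------


def svm_rbf_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    C: float = 1.0,
    gamma="scale",
    seed: int | None = None,
) -> CvReport:
    """Stratified k-fold CV of an RBF-SVM with per-fold standardization.

    ``y`` holds binary labels; the positive class is the one sorted last
    (e.g. "OA" against "HC").  Decision-function values drive the ROC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    positive = classes[-1]
    counts = [int((y == c).sum()) for c in classes]
    if min(counts) < k:
        raise ValueError(f"each class needs >= k={k} members, got {counts}")
    y_bin = (y == positive).astype(int)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, confusions = [], []
    all_scores, all_labels = [], []
    for fold, (tr, te) in enumerate(skf.split(X, y_bin)):
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)
        clf.fit(scaler.transform(X[tr]), y_bin[tr])
        scores = clf.decision_function(scaler.transform(X[te]))
        pred = (scores > 0).astype(int)
        truth = y_bin[te]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        m = metrics_from_confusion(tp, fn, tn, fp)
        m["auc"], _ = roc_auc(scores, truth)
        m["fold"] = fold
        rows.append(m)
        confusions.append((tp, fn, tn, fp))
        all_scores.append(scores)
        all_labels.append(truth)
    _, roc_points = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
    return CvReport(folds=pd.DataFrame(rows), confusions=confusions, roc_points=roc_points)
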
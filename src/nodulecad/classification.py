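"""Candidate classification with a thresholded epsilon-SVR (RBF kernel).

The classifier is a support-vector regression on +/-1 targets whose output
is thresholded at 0: nodule iff the regression score is non-negative. The
epsilon parameter of the epsilon-insensitive loss (``epsilon_p``, default
0.4) controls how aggressively the fit hugs the targets and thereby the
sensitivity/specificity trade-off. Training uses a balanced matrix (equal
numbers of nodules and non-nodules, 20 each by default) and per-feature
min-max normalization to [0, 1]; C and gamma are selected automatically by
cross-validated grid search.

Two normalization protocols are offered. The default fits the min-max
statistics on training data only and applies them to new data (leak-free
deployment). The transductive protocol (``transductive=True``) pools
training and new data before computing the statistics, then splits them
back; it is kept for fidelity to the original classification procedure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVR

__all__ = [
    "TrainedClassifier",
    "build_balanced_matrix",
    "select_representatives",
    "joint_normalize",
    "apply_normalization",
    "default_grid",
    "train_svm",
    "tune_threshold_for_sensitivity",
    "classify",
    "save_classifier",
    "load_classifier",
]

logger = logging.getLogger(__name__)


def _feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c != "label"]


@dataclass
class TrainedClassifier:
    """A fitted RBF epsilon-SVR plus the normalization it requires."""

    model: SVR
    C: float
    gamma: float
    epsilon_p: float
    norm_stats: pd.DataFrame  # index = feature names, columns = ["min", "max"]
    feature_names: list[str]
    decision_threshold: float = 0.0
    cv_accuracy: float | None = None
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not 0.0 <= self.epsilon_p < 1.0:
            raise ValueError(f"epsilon_p must be in [0, 1), got {self.epsilon_p}")
        if len(self.norm_stats) != len(self.feature_names):
            raise ValueError("norm_stats must cover every feature")


def build_balanced_matrix(matrix: pd.DataFrame, n_per_class: int = 20,
                          seed: int = 0) -> pd.DataFrame:
    """Sample ``n_per_class`` nodules (+1) and non-nodules (-1) without
    replacement; deterministic for a fixed seed."""
    if "label" not in matrix.columns:
        raise ValueError("matrix must carry a 'label' column (+1 nodule, -1 non-nodule)")
    rng = np.random.default_rng(seed)
    parts = []
    for lab in (1, -1):
        pool = matrix.index[matrix["label"] == lab].to_numpy()
        if len(pool) < n_per_class:
            raise ValueError(
                f"insufficient rows of class {lab:+d}: have {len(pool)}, "
                f"need {n_per_class}")
        chosen = rng.choice(pool, size=n_per_class, replace=False)
        parts.append(matrix.loc[chosen])
    balanced = pd.concat(parts)
    balanced.attrs["normalization"] = matrix.attrs.get("normalization", "raw")
    return balanced


def select_representatives(matrix: pd.DataFrame, n_per_class: int = 20
                           ) -> pd.DataFrame:
    """Balanced matrix of class representatives spanning each class's range.

    Rows of each class are ordered by total intensity (d8 when present,
    else the first feature column — a monotone proxy for lesion size) and
    picked at evenly spaced quantiles, so the smallest and largest
    exemplars of both classes always enter training. Deterministic; the
    counterpart of random sampling in ``build_balanced_matrix`` for
    protocols that train on extreme cases.
    """
    if "label" not in matrix.columns:
        raise ValueError("matrix must carry a 'label' column")
    proxy = "d8_sum_intensity" if "d8_sum_intensity" in matrix.columns \
        else _feature_columns(matrix)[0]
    parts = []
    for lab in (1, -1):
        pool = matrix[matrix["label"] == lab].sort_values(proxy)
        if len(pool) < n_per_class:
            raise ValueError(
                f"insufficient rows of class {lab:+d}: have {len(pool)}, "
                f"need {n_per_class}")
        idx = np.round(np.linspace(0, len(pool) - 1, n_per_class)).astype(int)
        for k in range(1, n_per_class):  # de-duplicate, keep increasing
            idx[k] = max(idx[k], idx[k - 1] + 1)
        for k in range(n_per_class - 1, 0, -1):
            idx[k - 1] = min(idx[k - 1], idx[k] - 1)
        parts.append(pool.iloc[idx])
    balanced = pd.concat(parts)
    balanced.attrs["normalization"] = matrix.attrs.get("normalization", "raw")
    return balanced


def joint_normalize(train: pd.DataFrame, new: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Min-max normalize train and new matrices with shared statistics.

    The per-feature min/max are computed over the CONCATENATION of both
    matrices (the transductive protocol); if ``new`` is empty or None the
    training matrix is normalized by its own range. Constant features map
    to 0. Returns (train', new', stats).
    """
    cols = _feature_columns(train)
    if new is not None and len(new) > 0:
        if _feature_columns(new) != cols:
            raise ValueError(
                f"feature columns differ: {cols} vs {_feature_columns(new)}")
        pooled = pd.concat([train[cols], new[cols]])
    else:
        pooled = train[cols]
    stats = pd.DataFrame({"min": pooled.min(), "max": pooled.max()})
    train_n = apply_normalization(train, stats)
    new_n = apply_normalization(new, stats) if new is not None else None
    return train_n, new_n, stats


def apply_normalization(matrix: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Apply stored min-max statistics to a matrix (labels pass through)."""
    out = matrix.copy()
    for c in stats.index:
        lo, hi = float(stats.loc[c, "min"]), float(stats.loc[c, "max"])
        if hi > lo:
            out[c] = (matrix[c] - lo) / (hi - lo)
        else:
            out[c] = 0.0
    out.attrs["normalization"] = "joint-normalized"
    return out


def invert_normalization(matrix: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    out = matrix.copy()
    for c in stats.index:
        lo, hi = float(stats.loc[c, "min"]), float(stats.loc[c, "max"])
        out[c] = matrix[c] * (hi - lo) + lo
    out.attrs["normalization"] = "raw"
    return out


def default_grid() -> tuple[list[float], list[float]]:
    """The automatic-selection search grid: C in 2^-5..2^15, gamma in
    2^-15..2^3, both in steps of x4."""
    c_grid = [2.0 ** e for e in range(-5, 16, 2)]
    gamma_grid = [2.0 ** e for e in range(-15, 4, 2)]
    return c_grid, gamma_grid


def _cv_accuracy(X, y, C, gamma, epsilon, seed, folds, repeats=3):
    """Repeated stratified k-fold accuracy of sign(prediction).

    A single shuffle is too noisy to rank kernel parameters on the small
    balanced matrices this protocol uses, so the score is averaged over
    ``repeats`` reshuffles.
    """
    correct = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + 1000 * rep)
        for train_idx, test_idx in skf.split(X, y):
            model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
            model.fit(X[train_idx], y[train_idx])
            pred = np.where(model.predict(X[test_idx]) >= 0.0, 1, -1)
            correct += int((pred == y[test_idx]).sum())
    return correct / (len(y) * repeats)


def train_svm(balanced: pd.DataFrame, epsilon_p: float = 0.4, seed: int = 0,
              C: float | None = None, gamma: float | None = None,
              cv_folds: int = 5) -> TrainedClassifier:
    """Fit the thresholded epsilon-SVR on a normalized balanced matrix.

    When ``C``/``gamma`` are not given they are selected by exhaustive grid
    search maximizing the ``cv_folds``-fold cross-validated accuracy of
    sign(prediction); ties go to the first grid point. Deterministic for a
    fixed seed.
    """
    if not 0.0 <= epsilon_p < 1.0:
        raise ValueError(f"epsilon_p must be in [0, 1), got {epsilon_p}")
    cols = _feature_columns(balanced)
    if "label" not in balanced.columns:
        raise ValueError("balanced matrix must carry a 'label' column")
    X = balanced[cols].to_numpy(dtype=np.float64)
    y = balanced["label"].to_numpy(dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training labels are single-class ({classes.tolist()})")

    cv_acc = None
    if C is None or gamma is None:
        folds = int(min(cv_folds, counts.min()))
        if folds < 2:
            raise ValueError("need at least 2 samples per class for grid search")
        c_grid, gamma_grid = default_grid()
        best = (-np.inf, None, None)
        for c_val in c_grid:
            for g_val in gamma_grid:
                acc = _cv_accuracy(X, y, c_val, g_val, epsilon_p, seed, folds)
                if acc > best[0]:
                    best = (acc, c_val, g_val)
        cv_acc, C, gamma = best
        logger.info("grid search: C=%g gamma=%g (cv accuracy %.3f)", C, gamma, cv_acc)

    model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon_p)
    model.fit(X, y.astype(np.float64))
    stats = pd.DataFrame({"min": np.zeros(len(cols)), "max": np.ones(len(cols))},
                         index=pd.Index(cols))
    return TrainedClassifier(model=model, C=float(C), gamma=float(gamma),
                             epsilon_p=float(epsilon_p), norm_stats=stats,
                             feature_names=list(cols), cv_accuracy=cv_acc,
                             train_X=X, train_y=y)


def tune_threshold_for_sensitivity(clf: TrainedClassifier,
                                   balanced: pd.DataFrame,
                                   fn_weight: float = 2.0,
                                   seed: int = 0, cv_folds: int = 5) -> float:
    """Pick the decision threshold from training-fold scores only.

    Held-out regression scores of the balanced matrix (k-fold, at the
    classifier's fixed C/gamma/epsilon) are swept for the threshold, capped
    at 0, minimizing ``fn_weight * FN + FP``: missed nodules cost more than
    false alarms, so the operating point settles just above the non-nodule
    score band rather than mid-gap. This reproduces choosing a
    high-sensitivity operating point on training data alone.
    """
    cols = clf.feature_names
    X = balanced[cols].to_numpy(dtype=np.float64)
    y = balanced["label"].to_numpy(dtype=np.int64)
    folds = int(min(cv_folds, np.bincount((y == 1).astype(int)).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores, labels = [], []
    for train_idx, test_idx in skf.split(X, y):
        m = SVR(kernel="rbf", C=clf.C, gamma=clf.gamma, epsilon=clf.epsilon_p)
        m.fit(X[train_idx], y[train_idx].astype(np.float64))
        scores.extend(m.predict(X[test_idx]).tolist())
        labels.extend(y[test_idx].tolist())
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    # candidate thresholds: midpoints between adjacent held-out scores
    uniq = np.sort(np.unique(scores))
    cands = np.concatenate([[uniq[0] - 0.1],
                            (uniq[:-1] + uniq[1:]) / 2.0, [0.0]])
    best_cost, optimal = np.inf, []
    for t in cands:
        if t > 0.0:
            continue
        fn = int(((scores < t) & (labels == 1)).sum())
        fp = int(((scores >= t) & (labels == -1)).sum())
        cost = fn_weight * fn + fp
        if cost < best_cost:
            best_cost, optimal = cost, [float(t)]
        elif cost == best_cost:
            optimal.append(float(t))
    # max-margin tie-break: center of the optimal-cost interval
    best_t = float(min(0.0, (min(optimal) + max(optimal)) / 2.0))
    clf.decision_threshold = best_t
    logger.info("decision threshold tuned to %.3f (cv cost %g)", best_t, best_cost)
    return best_t


def classify(clf: TrainedClassifier, new: pd.DataFrame
             ) -> tuple[np.ndarray, np.ndarray]:
    """Score and label a normalized feature matrix.

    Returns ``(labels, scores)`` with label +1 (nodule) iff the SVR score is
    at or above ``clf.decision_threshold``. Inputs far outside [0, 1] draw a
    warning: they were probably not normalized with the classifier's stats.
    """
    if len(new) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
    X = new[clf.feature_names].to_numpy(dtype=np.float64)
    if X.min() < -0.1 or X.max() > 1.1:
        logger.warning("classify: feature values outside [-0.1, 1.1]; "
                       "input may not be normalized")
    scores = clf.model.predict(X)
    labels = np.where(scores >= clf.decision_threshold, 1, -1)
    return labels, scores


def save_classifier(clf: TrainedClassifier, path: str) -> None:
    """Persist the classifier as JSON (params, stats and training data; the
    SVR refits deterministically on load)."""
    payload = {
        "C": clf.C, "gamma": clf.gamma, "epsilon_p": clf.epsilon_p,
        "decision_threshold": clf.decision_threshold,
        "cv_accuracy": clf.cv_accuracy,
        "feature_names": clf.feature_names,
        "norm_stats": {c: [float(clf.norm_stats.loc[c, "min"]),
                           float(clf.norm_stats.loc[c, "max"])]
                       for c in clf.norm_stats.index},
        "train_X": np.asarray(clf.train_X).tolist(),
        "train_y": np.asarray(clf.train_y).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_classifier(path: str) -> TrainedClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    X = np.asarray(payload["train_X"], dtype=np.float64)
    y = np.asarray(payload["train_y"], dtype=np.int64)
    model = SVR(kernel="rbf", C=payload["C"], gamma=payload["gamma"],
                epsilon=payload["epsilon_p"])
    model.fit(X, y.astype(np.float64))
    stats = pd.DataFrame(
        {"min": {c: v[0] for c, v in payload["norm_stats"].items()},
         "max": {c: v[1] for c, v in payload["norm_stats"].items()}})
    stats = stats.loc[payload["feature_names"]]
    return TrainedClassifier(
        model=model, C=payload["C"], gamma=payload["gamma"],
        epsilon_p=payload["epsilon_p"], norm_stats=stats,
        feature_names=payload["feature_names"],
        decision_threshold=payload["decision_threshold"],
        cv_accuracy=payload.get("cv_accuracy"), train_X=X, train_y=y)
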
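"""Scoring against ground truth: confusion counts, the standard metric
formulas, leave-two-out cross-validation, and the ROC-over-epsilon sweep.

The hit criterion is geometric: a candidate predicted as a nodule counts as
a true positive when its centroid lies within the ground-truth radius of
some planted nodule; each truth can be claimed by at most one candidate
(nearest first). Sensitivity, specificity and accuracy follow the usual
definitions TP/(TP+FN), TN/(TN+FP), (TP+TN)/total, reported as percentages
rounded half-up to two decimals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .classification import (apply_normalization, build_balanced_matrix,
                             classify, joint_normalize, train_svm)
from .phantom import NoduleTruth

__all__ = [
    "ConfusionCounts",
    "match_candidates_to_truth",
    "metrics",
    "fp_per_scan",
    "leave_two_out_cv",
    "roc_over_epsilon",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def match_candidates_to_truth(centroids_mm, predicted_labels,
                              truths: list[NoduleTruth]) -> ConfusionCounts:
    """Match predicted nodules to planted nodules, nearest first.

    A predicted-nodule candidate is TP when its centroid falls within the
    radius of an unclaimed truth; remaining predicted nodules are FP.
    Unclaimed truths are FN. Every predicted non-nodule counts as TN, so
    TP + FP + TN equals the number of candidates.
    """
    centroids = np.asarray(centroids_mm, dtype=np.float64).reshape(-1, 3)
    labels = np.asarray(predicted_labels)
    if len(centroids) != len(labels):
        raise ValueError("one label per candidate required")
    nodule_idx = np.flatnonzero(labels == 1)

    pairs = []
    for ci in nodule_idx:
        for ti, truth in enumerate(truths):
            dist = float(np.linalg.norm(centroids[ci] - np.asarray(truth.center_mm)))
            if dist <= truth.radius_mm:
                pairs.append((dist, int(ci), ti))
    pairs.sort()
    used_c, used_t = set(), set()
    tp = 0
    for dist, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tp += 1
    fp = len(nodule_idx) - tp
    fn = len(truths) - len(used_t)
    tn = int((labels == -1).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    value = Decimal(numerator) / Decimal(denominator) * 100
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics(cc: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy
    (TP+TN)/total as percentages (2 decimals, half-up); a zero denominator
    yields None (undefined), never 0."""
    return {
        "sensitivity": _pct(cc.tp, cc.tp + cc.fn),
        "specificity": _pct(cc.tn, cc.tn + cc.fp),
        "accuracy": _pct(cc.tp + cc.tn, cc.total),
    }


def fp_per_scan(cc: ConfusionCounts, n_scans: int) -> float:
    """Average number of false positives per examination."""
    if n_scans < 1:
        raise ValueError(f"n_scans must be >= 1, got {n_scans}")
    return cc.fp / n_scans


@dataclass
class LtoCvResult:
    counts: ConfusionCounts
    n_folds: int
    n_skipped: int
    scores: np.ndarray  # per held-out prediction
    labels: np.ndarray  # matching true labels
    pairs: list[tuple[int, int]] = None  # evaluated test pairs (row positions)


def leave_two_out_cv(matrix: pd.DataFrame, epsilon_p: float = 0.4, seed: int = 0,
                     max_folds: int = 500, n_per_class: int = 20,
                     transductive: bool = False,
                     optimize_each_fold: bool = False) -> LtoCvResult:
    """Leave-two-out cross-validation of the classification stage.

    All C(n, 2) two-element test sets are enumerated when that count is at
    most ``max_folds``; otherwise ``max_folds`` distinct pairs are sampled
    with ``seed``. Per fold: a balanced matrix is drawn from the training
    rows, data are min-max normalized (pooled with the test pair when
    ``transductive``), the SVR is fitted, and the two held-out rows are
    classified. C/gamma are grid-searched once on the full data unless
    ``optimize_each_fold``. Folds whose training side lacks 2 rows of
    either class are skipped with a warning.
    """
    if len(matrix) < 4:
        raise ValueError("need at least 4 labeled rows")
    if "label" not in matrix.columns:
        raise ValueError("matrix must carry a 'label' column")
    n = len(matrix)
    all_pairs = list(itertools.combinations(range(n), 2))
    rng = np.random.default_rng(seed)
    if len(all_pairs) > max_folds:
        chosen = rng.choice(len(all_pairs), size=max_folds, replace=False)
        pairs = [all_pairs[i] for i in sorted(chosen)]
    else:
        pairs = all_pairs

    fixed_c = fixed_gamma = None
    if not optimize_each_fold:
        counts = matrix["label"].value_counts()
        n_bal = int(min(n_per_class, counts.min()))
        balanced = build_balanced_matrix(matrix, n_bal, seed=seed)
        bal_n, _, _ = joint_normalize(balanced)
        probe = train_svm(bal_n, epsilon_p=epsilon_p, seed=seed)
        fixed_c, fixed_gamma = probe.C, probe.gamma

    total = ConfusionCounts()
    scores_out, labels_out = [], []
    n_skipped = 0
    for fold_seed, (i, j) in enumerate(pairs):
        test = matrix.iloc[[i, j]]
        train = matrix.drop(matrix.index[[i, j]])
        counts = train["label"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            logger.warning("fold (%d,%d) skipped: training side lacks 2 rows "
                           "of each class", i, j)
            n_skipped += 1
            continue
        n_bal = int(min(n_per_class, counts.min()))
        balanced = build_balanced_matrix(train, n_bal, seed=seed + fold_seed)
        if transductive:
            bal_n, test_n, _ = joint_normalize(balanced, test)
        else:
            bal_n, _, stats = joint_normalize(balanced)
            test_n = apply_normalization(test, stats)
        clf = train_svm(bal_n, epsilon_p=epsilon_p, seed=seed,
                        C=fixed_c, gamma=fixed_gamma)
        pred, scores = classify(clf, test_n)
        truth = test["label"].to_numpy(dtype=np.int64)
        total = total + ConfusionCounts(
            tp=int(((pred == 1) & (truth == 1)).sum()),
            tn=int(((pred == -1) & (truth == -1)).sum()),
            fp=int(((pred == 1) & (truth == -1)).sum()),
            fn=int(((pred == -1) & (truth == 1)).sum()))
        scores_out.extend(scores.tolist())
        labels_out.extend(truth.tolist())
    return LtoCvResult(total, len(pairs) - n_skipped, n_skipped,
                       np.asarray(scores_out), np.asarray(labels_out),
                       pairs=pairs)


def roc_over_epsilon(matrix: pd.DataFrame, epsilons, seed: int = 0,
                     **cv_kwargs) -> list[dict]:
    """One cross-validated operating point per epsilon, plus the full ROC
    obtained by sweeping the decision threshold over the fold scores."""
    epsilons = list(epsilons)
    if not epsilons:
        raise ValueError("epsilons must be nonempty")
    for eps in epsilons:
        if not 0.0 <= eps < 1.0:
            raise ValueError(f"epsilon must be in [0, 1), got {eps}")
    from sklearn.metrics import roc_curve

    points = []
    for eps in epsilons:
        res = leave_two_out_cv(matrix, epsilon_p=eps, seed=seed, **cv_kwargs)
        m = metrics(res.counts)
        spec = m["specificity"]
        if len(np.unique(res.labels)) == 2:
            fpr, tpr, thr = roc_curve(res.labels, res.scores)
        else:
            fpr = tpr = thr = np.empty(0)
        points.append({
            "epsilon": eps,
            "sensitivity": m["sensitivity"],
            "one_minus_specificity": None if spec is None else round(100 - spec, 2),
            "counts": res.counts,
            "curve": {"fpr": fpr, "tpr": tpr, "thresholds": thr},
        })
    return points
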
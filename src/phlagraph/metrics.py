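"""Classification metrics for immunogenicity predictors.

Sensitivity and F1 are thresholded confusion-matrix metrics (default
operating threshold 0.5); TopK is the fraction of true positives among the
K highest-scoring predictions (stable sort, ties keep input order); AUC is
the rank-based concordance probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


@dataclass
class LabeledScores:
    """Paired prediction scores and binary labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.ndim != 1 or self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if self.scores.size == 0:
            raise ValueError("empty score list")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(int)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.labels.size - self.labels.sum())


def sensitivity(ls: LabeledScores, threshold: float = 0.5) -> float:
    """TP / (TP + FN), counting score >= threshold as a positive call."""
    if ls.n_positive == 0:
        raise ValueError("sensitivity undefined without positive labels")
    calls = ls.scores >= threshold
    tp = int(np.sum(calls & (ls.labels == 1)))
    return tp / ls.n_positive


def f1(ls: LabeledScores, threshold: float = 0.5) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0 (convention)."""
    calls = ls.scores >= threshold
    tp = int(np.sum(calls & (ls.labels == 1)))
    fp = int(np.sum(calls & (ls.labels == 0)))
    fn = int(np.sum(~calls & (ls.labels == 1)))
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def topk(ls: LabeledScores, k: int) -> float:
    """Fraction of positives among the k highest-scoring items.

    Sorting is stable on descending score, so tied items keep input order.
    """
    n = ls.scores.size
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    order = np.argsort(-ls.scores, kind="stable")
    return float(ls.labels[order[:k]].sum() / k)


def roc_auc(ls: LabeledScores) -> float:
    """Rank-based AUC (concordance probability, ties counted half)."""
    n_pos, n_neg = ls.n_positive, ls.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(ls.scores)  # average ranks handle ties at 1/2
    pos_rank_sum = ranks[ls.labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(ls: LabeledScores) -> np.ndarray:
    """ROC curve as an (n, 2) array of (FPR, TPR) points."""
    fpr, tpr, _ = roc_curve(ls.labels, ls.scores)
    return np.stack([fpr, tpr], axis=1)
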
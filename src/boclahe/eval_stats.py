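"""Evaluation utilities: mask overlap, classification metrics from
confusion tables, rank-based ROC AUC, and one-way ANOVA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import rankdata

from boclahe.errors import ArgumentError, DegenerateInputError

__all__ = [
    "jaccard",
    "dice",
    "ConfusionTable",
    "classification_metrics",
    "auc_roc",
    "anova_oneway",
]


def _check_pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ArgumentError("masks must have the same shape")
    return a, b


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B|; defined as 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def dice(a, b) -> float:
    """2|A∩B| / (|A| + |B|); defined as 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    total = np.count_nonzero(a) + np.count_nonzero(b)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / total


@dataclass(frozen=True)
class ConfusionTable:
    """Square count grid: rows = true class, cols = predicted class."""

    counts: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ArgumentError("confusion table must be square")
        if np.any(c < 0):
            raise ArgumentError("confusion counts must be non-negative")
        labels = self.labels or tuple(range(c.shape[0]))
        if len(labels) != c.shape[0]:
            raise ArgumentError("labels must match table size")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "labels", tuple(labels))


def classification_metrics(table: ConfusionTable) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1.

    Per-class precision (recall) is 0 when its column (row) is empty;
    F1 is 0 when precision + recall is 0.
    """
    c = table.counts
    total = int(c.sum())
    if total == 0:
        raise ArgumentError("confusion table is empty")
    tp = np.diag(c).astype(float)
    col = c.sum(axis=0).astype(float)
    row = c.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "per_class": {
            str(lbl): {"precision": float(p), "recall": float(r), "f1": float(f)}
            for lbl, p, r, f in zip(table.labels, precision, recall, f1)
        },
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


def auc_roc(labels, scores) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted 1/2 (Mann-Whitney rank formulation)."""
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ArgumentError("labels and scores must have the same length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ArgumentError("both classes must be present")
    ranks = rankdata(s)
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def anova_oneway(groups: dict) -> tuple:
    """One-way ANOVA over named groups of metric values.

    Returns ``(F, p)`` with F = (between-group SS/df1)/(within-group
    SS/df2) and p from the upper tail of the F distribution.
    """
    arrays = [np.asarray(v, dtype=float).ravel() for v in groups.values()]
    if len(arrays) < 2:
        raise ArgumentError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ArgumentError("each group needs at least 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df1 = len(arrays) - 1
    df2 = len(all_vals) - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            raise DegenerateInputError("all groups are constant and equal")
        raise DegenerateInputError("zero within-group variance")
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(f_dist.sf(f_stat, df1, df2))
    return float(f_stat), p
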
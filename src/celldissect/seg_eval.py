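"""Instance-segmentation accuracy: IoU object matching and F1 at a threshold.

Predicted and ground-truth objects are matched one-to-one; a pair is a
true positive only if its intersection-over-union (Jaccard index) strictly
exceeds the threshold t (default 0.7).  Precision, recall and F1 follow:

    precision(t) = TP / (TP + FP)
    recall(t)    = TP / (TP + FN)
    F1(t)        = 2 * precision * recall / (precision + recall)

At t >= 0.5 each object can exceed the threshold with at most one partner,
so the matching is unique; for generality below 0.5 the matching maximizes
the number of matched pairs, then total IoU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from .segmentation import LabelMask

__all__ = ["MatchResult", "EvalScores", "iou", "pairwise_iou", "match_objects", "f1_scores", "evaluate_batch"]


@dataclass(frozen=True)
class MatchResult:
    threshold: float
    matches: list[tuple[int, int, float]]  # (pred_label, gt_label, IoU)
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class EvalScores:
    precision: float
    recall: float
    f1: float


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a∩b| / (|a| + |b| − |a∩b|) of two pixel sets.

    Pixel sets are (n, 2) integer arrays of (row, col).  Two empty sets
    have no defined overlap and are rejected.
    """
    a = np.asarray(a).reshape(-1, 2)
    b = np.asarray(b).reshape(-1, 2)
    if a.size == 0 and b.size == 0:
        raise ValueError("IoU of two empty pixel sets is undefined")
    if a.size == 0 or b.size == 0:
        return 0.0
    sa = {tuple(p) for p in a.tolist()}
    sb = {tuple(p) for p in b.tolist()}
    inter = len(sa & sb)
    return inter / (len(sa) + len(sb) - inter)


def pairwise_iou(pred: LabelMask, gt: LabelMask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IoU matrix between every predicted and ground-truth object.

    Returns ``(pred_labels, gt_labels, iou_matrix)`` where
    ``iou_matrix[i, j]`` is the IoU of ``pred_labels[i]`` with
    ``gt_labels[j]``.  Computed from the joint label histogram, so cost is
    linear in pixels regardless of object count.
    """
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("pred and gt masks must have the same shape")
    p = pred.labels.ravel()
    g = gt.labels.ravel()
    pred_labels = np.unique(p[p > 0])
    gt_labels = np.unique(g[g > 0])
    if pred_labels.size == 0 or gt_labels.size == 0:
        return pred_labels, gt_labels, np.zeros((pred_labels.size, gt_labels.size))
    pi = np.searchsorted(pred_labels, p)
    gi = np.searchsorted(gt_labels, g)
    both = (p > 0) & (g > 0)
    inter = sparse.coo_matrix(
        (np.ones(both.sum()), (pi[both], gi[both])),
        shape=(pred_labels.size, gt_labels.size),
    ).toarray()
    area_p = np.bincount(pi[p > 0], minlength=pred_labels.size).astype(float)
    area_g = np.bincount(gi[g > 0], minlength=gt_labels.size).astype(float)
    union = area_p[:, None] + area_g[None, :] - inter
    return pred_labels, gt_labels, inter / union


def match_objects(pred: LabelMask, gt: LabelMask, t: float = 0.7) -> MatchResult:
    """One-to-one matching of predicted to ground-truth objects at IoU > t.

    Among all matchings restricted to pairs with IoU strictly above t, the
    returned one maximizes the number of matched pairs, breaking ties by
    maximal total IoU; remaining ambiguities resolved deterministically by
    ascending (gt label, pred label).
    """
    if not (0 < t <= 1):
        raise ValueError("threshold must be in (0, 1]")
    pred_labels, gt_labels, mat = pairwise_iou(pred, gt)
    eligible = mat > t
    matches: list[tuple[int, int, float]] = []
    if eligible.any():
        # reward K + IoU with K > max possible total IoU makes cardinality
        # dominate; linear_sum_assignment then maximizes total IoU among
        # maximum-cardinality matchings
        K = float(max(mat.shape) + 1)
        reward = np.where(eligible, K + mat, 0.0)
        rows, cols = linear_sum_assignment(reward, maximize=True)
        for i, j in zip(rows, cols):
            if eligible[i, j]:
                matches.append((int(pred_labels[i]), int(gt_labels[j]), float(mat[i, j])))
        matches.sort(key=lambda m: (-m[2], m[1], m[0]))
    tp = len(matches)
    return MatchResult(
        threshold=t,
        matches=matches,
        tp=tp,
        fp=int(pred_labels.size) - tp,
        fn=int(gt_labels.size) - tp,
    )


def f1_scores(m: MatchResult) -> EvalScores:
    """Precision/recall/F1 from matched counts.

    0/0 conventions: a ratio with zero denominator is 1 (vacuously
    perfect); F1 is 1 only when both masks are empty, otherwise 0 when
    TP = 0.
    """
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 1.0
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 1.0
    if m.tp == 0:
        f1 = 1.0 if (m.fp == 0 and m.fn == 0) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalScores(precision=precision, recall=recall, f1=f1)


def evaluate_batch(
    pairs: list[tuple[LabelMask, LabelMask]], t: float = 0.7
) -> tuple[list[EvalScores], float, float]:
    """Per-image scores plus mean F1 and its standard error over images.

    The s.e.m. is sd / sqrt(n) across images (sample sd, n − 1), the
    standard way multi-image segmentation benchmarks are reported.
    """
    if not pairs:
        raise ValueError("evaluate_batch requires at least one (pred, gt) pair")
    scores = [f1_scores(match_objects(p, g, t)) for p, g in pairs]
    f1s = np.array([s.f1 for s in scores])
    mean = float(f1s.mean())
    sem = float(f1s.std(ddof=1) / np.sqrt(len(f1s))) if len(f1s) > 1 else 0.0
    return scores, mean, sem
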
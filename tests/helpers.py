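"""Independent oracles and random-instance generators shared by the tests.

Everything here is deliberately written from first principles (set
arithmetic, exhaustive enumeration) so it cannot share a bug with the
library code it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from celldissect import LabelMask


def pixel_sets(mask: LabelMask) -> dict[int, set[tuple[int, int]]]:
    out: dict[int, set[tuple[int, int]]] = {}
    for (r, c), v in np.ndenumerate(mask.labels):
        if v > 0:
            out.setdefault(int(v), set()).add((r, c))
    return out


def set_iou(a: set, b: set) -> float:
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union if union else 0.0


def brute_force_match(pred: LabelMask, gt: LabelMask, t: float) -> tuple[int, float]:
    """Exhaustive maximum-cardinality matching over all one-to-one assignments.

    Returns (max number of matched pairs with IoU > t, max total IoU among
    maximum-cardinality matchings).
    """
    ps = pixel_sets(pred)
    gs = pixel_sets(gt)
    pred_ids = sorted(ps)
    gt_ids = sorted(gs)
    small, large, flipped = (pred_ids, gt_ids, False)
    if len(gt_ids) < len(pred_ids):
        small, large, flipped = gt_ids, pred_ids, True
    best_n, best_sum = 0, 0.0
    for perm in itertools.permutations(large, len(small)):
        n, s = 0, 0.0
        for a, b in zip(small, perm):
            pa, ga = (a, b) if not flipped else (b, a)
            v = set_iou(ps[pa], gs[ga])
            if v > t:
                n += 1
                s += v
        if n > best_n or (n == best_n and s > best_sum):
            best_n, best_sum = n, s
    return best_n, best_sum


def brute_force_scores(pred: LabelMask, gt: LabelMask, t: float) -> tuple[float, float, float]:
    """Precision/recall/F1 from the exhaustive matching, computed independently."""
    tp, _ = brute_force_match(pred, gt, t)
    n_pred = len(pixel_sets(pred))
    n_gt = len(pixel_sets(gt))
    fp, fn = n_pred - tp, n_gt - tp
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    if tp == 0:
        f1 = 1.0 if (fp == 0 and fn == 0) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def random_label_mask(rng: np.random.Generator, shape=(14, 14), max_objects=6) -> LabelMask:
    """Random small instance mask: overlapping rectangles, later labels overwrite."""
    labels = np.zeros(shape, dtype=np.int32)
    n = rng.integers(0, max_objects + 1)
    for lab in range(1, n + 1):
        h = rng.integers(2, 6)
        w = rng.integers(2, 6)
        r = rng.integers(0, shape[0] - h)
        c = rng.integers(0, shape[1] - w)
        labels[r : r + h, c : c + w] = lab
    # overwriting may erase labels entirely; keep as-is (non-contiguous ids are legal)
    return LabelMask(labels, 1.0)


def brute_force_open_tsp(points: np.ndarray, start: np.ndarray) -> float:
    """Optimal open-path travel from start through all points, by enumeration."""
    n = len(points)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        path = np.vstack([start, points[list(perm)]])
        d = float(np.sqrt(((np.diff(path, axis=0)) ** 2).sum(axis=1)).sum())
        best = min(best, d)
    return best


def random_simple_polygon(rng: np.random.Generator, n_vertices=8, radius=10.0) -> np.ndarray:
    """Star-shaped (hence simple) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    center = rng.uniform(-20, 20, 2)
    return np.column_stack([center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)])


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) by direct summation."""
    from math import comb

    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1) if n - i <= N - K) / comb(N, n)
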
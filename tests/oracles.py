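"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive every quantity from first principles —
full rescans, exhaustive pair counting — and share no code with the
package internals they verify.
"""

from __future__ import annotations

import numpy as np


def rescan_stats(labels: np.ndarray, cube_data: np.ndarray):
    """Areas, mean spectra and boundary lengths by brute-force rescan."""
    ids = np.unique(labels[labels >= 0])
    areas = {i: int((labels == i).sum()) for i in ids}
    means = {i: cube_data[labels == i].mean(axis=0) for i in ids}
    boundary: dict[tuple[int, int], int] = {}
    rows, cols = labels.shape
    for r in range(rows):
        for c in range(cols):
            a = labels[r, c]
            if a < 0:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < rows and cc < cols:
                    b = labels[rr, cc]
                    if b >= 0 and b != a:
                        key = (min(a, b), max(a, b))
                        boundary[key] = boundary.get(key, 0) + 1
    return areas, means, boundary


def direct_cost(areas, means, boundary, i: int, j: int) -> float:
    key = (min(i, j), max(i, j))
    diff = means[i] - means[j]
    return (areas[i] * areas[j] / (areas[i] + areas[j])) * float(
        diff @ diff
    ) / boundary[key]


def brute_force_lambda_merge(labels: np.ndarray, cube_data: np.ndarray,
                             threshold: float) -> np.ndarray:
    """Full-rescan greedy merging: recompute every pairwise cost from the
    label image at every step, merge the global minimum (ties by smallest
    (min id, max id)) while it stays below the threshold."""
    labels = labels.copy()
    while True:
        areas, means, boundary = rescan_stats(labels, cube_data)
        best = None
        for (i, j) in sorted(boundary):
            cost = direct_cost(areas, means, boundary, i, j)
            cand = (cost, i, j)
            if best is None or cand < best:
                best = cand
        if best is None or not best[0] < threshold:
            return labels
        labels[labels == best[2]] = best[1]


def canonical_partition(labels: np.ndarray) -> np.ndarray:
    """Relabel by first occurrence so two partitions compare directly."""
    out = np.full(labels.shape, -1, dtype=int)
    mapping: dict[int, int] = {}
    for idx, val in enumerate(labels.ravel()):
        if val >= 0 and val not in mapping:
            mapping[val] = len(mapping)
    flat = labels.ravel()
    out_flat = out.ravel()
    for k in range(len(flat)):
        if flat[k] >= 0:
            out_flat[k] = mapping[flat[k]]
    return out


def random_rect_partition(rng: np.random.Generator, shape=(8, 8),
                          max_segments: int = 6) -> np.ndarray:
    """Random guillotine partition into connected rectangles (<= max)."""
    rects = [(0, 0, shape[0], shape[1])]
    target = int(rng.integers(2, max_segments + 1))
    guard = 0
    while len(rects) < target and guard < 100:
        guard += 1
        k = int(rng.integers(len(rects)))
        r0, c0, h, w = rects[k]
        if h < 2 and w < 2:
            continue
        rects.pop(k)
        if h >= 2 and (w < 2 or rng.random() < 0.5):
            cut = int(rng.integers(1, h))
            rects += [(r0, c0, cut, w), (r0 + cut, c0, h - cut, w)]
        else:
            cut = int(rng.integers(1, w))
            rects += [(r0, c0, h, cut), (r0, c0 + cut, h, w - cut)]
    labels = np.empty(shape, dtype=int)
    for i, (r0, c0, h, w) in enumerate(rects):
        labels[r0:r0 + h, c0:c0 + w] = i
    return labels


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray,
                     lower_is_positive: bool = True) -> float:
    """AUC by exhaustive pair counting (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p == q:
                wins += 0.5
            elif (p < q) == lower_is_positive:
                wins += 1.0
    return wins / (len(pos) * len(neg))
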
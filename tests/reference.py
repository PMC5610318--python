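"""Naive reference implementations used as independent oracles.

These deliberately avoid spatial indexing and vectorized bookkeeping: each
is the textbook double loop, so agreement with the package implementations
checks the indexed fast paths against first principles.
"""
from __future__ import annotations

import numpy as np


def naive_mean_shift_labels(
    points: np.ndarray,
    bandwidth: float,
    conv_tol: float = 0.01,
    merge_tol: float = 1.0,
    max_iter: int = 500,
) -> np.ndarray:
    """Per-point square-window mean shift without any spatial index."""
    points = np.asarray(points, float)
    n = len(points)
    finals = np.empty_like(points)
    for i in range(n):
        pos = points[i].copy()
        for _ in range(max_iter):
            inside = (np.abs(points[:, 0] - pos[0]) <= bandwidth) & (
                np.abs(points[:, 1] - pos[1]) <= bandwidth
            )
            new = points[inside].mean(axis=0)
            shift = np.hypot(*(new - pos))
            pos = new
            if shift < conv_tol:
                break
        finals[i] = pos
    # single-linkage grouping of final positions within merge_tol
    labels = np.full(n, -1)
    next_label = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = next_label
        while stack:
            k = stack.pop()
            d = np.hypot(finals[:, 0] - finals[k, 0], finals[:, 1] - finals[k, 1])
            for j in np.flatnonzero((d <= merge_tol) & (labels < 0)):
                labels[j] = next_label
                stack.append(j)
        next_label += 1
    return labels


def naive_hull_area(points: np.ndarray) -> float:
    """Convex hull area by testing every directed pair as a hull edge."""
    pts = np.unique(np.asarray(points, float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cross = (pts[:, 0] - pts[i, 0]) * (pts[j, 1] - pts[i, 1]) - (
                pts[:, 1] - pts[i, 1]
            ) * (pts[j, 0] - pts[i, 0])
            if (cross <= 1e-9).all():  # all points right of / on edge i->j
                edges.append((i, j))
    if not edges:
        return 0.0
    nxt = dict(edges)
    start = edges[0][0]
    order = [start]
    while True:
        nx = nxt[order[-1]]
        if nx == start:
            break
        order.append(nx)
        if len(order) > n:
            return 0.0  # collinear degeneracy
    hull = pts[order]
    x, y = hull[:, 0], hull[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def naive_ripley_counts(points: np.ndarray, roi, r_values: np.ndarray) -> np.ndarray:
    """The literal double sum over interior i and all j != i, per r."""
    pts = np.asarray(points, float)
    edge = roi.edge_distance(pts[:, 0], pts[:, 1])
    out = []
    for r in r_values:
        total = 0
        for i in range(len(pts)):
            if edge[i] >= r:
                for j in range(len(pts)):
                    if j != i and np.hypot(*(pts[i] - pts[j])) < r:
                        total += 1
        out.append(total)
    return np.asarray(out, float)


def partition_of(labels: np.ndarray) -> set[frozenset]:
    """Label-invariant representation of a clustering."""
    groups: dict[int, set] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(idx)
    return {frozenset(v) for v in groups.values()}
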
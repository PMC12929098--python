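"""Independent brute-force oracles used by the test suite only."""

import math

import numpy as np


def brute_force_purity(points, labels, k, metric="euclidean", binarize_hamming=True):
    """O(N^2) neighbor enumeration with explicit per-pair distances.

    Ties at the k-th distance break by ascending sample index; the query
    point is excluded. Kept deliberately loop-based and separate from the
    package implementation.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    n = len(points)
    if metric == "hamming" and binarize_hamming:
        med = [float(np.median(points[:, d])) for d in range(points.shape[1])]
        points = np.array(
            [[1.0 if points[i, d] > med[d] else 0.0 for d in range(points.shape[1])]
             for i in range(n)]
        )

    def dist(a, b):
        if metric == "euclidean":
            return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        if metric == "manhattan":
            return sum(abs(x - y) for x, y in zip(a, b))
        if metric == "hamming":
            return sum(1.0 for x, y in zip(a, b) if x != y) / len(a)
        if metric == "cosine":
            na = math.sqrt(sum(x * x for x in a))
            nb = math.sqrt(sum(y * y for y in b))
            return 1.0 - sum(x * y for x, y in zip(a, b)) / (na * nb)
        raise ValueError(metric)

    total = 0.0
    for i in range(n):
        ranked = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (dist(points[i], points[j]), j),
        )[:k]
        total += sum(1 for j in ranked if labels[j] == labels[i]) / k
    return total / n


def trapezoid_integral(recall, precision):
    """Independent numeric integration of a PR curve via numpy's
    trapezoidal integrator over recall-sorted points."""
    order = np.argsort(recall, kind="stable")
    return float(np.trapezoid(np.asarray(precision)[order], np.asarray(recall)[order]))
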
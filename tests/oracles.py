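"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: OLS via the
explicit normal equations / two-moment formulas, and agglomerative
complete-linkage clustering as a naive O(n^3) merge loop.
"""

from __future__ import annotations

import numpy as np


def ols_two_moment(x, y) -> tuple[float, float]:
    """Simple-regression slope/intercept from raw first and second moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = (x * x).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


def ols_normal_equations(x_matrix, y) -> np.ndarray:
    """Multiple-regression coefficients [intercept, slopes] via (X'X)^-1 X'y."""
    x = np.asarray(x_matrix, float)
    design = np.column_stack([np.ones(len(x)), x])
    return np.linalg.solve(design.T @ design, design.T @ np.asarray(y, float))


def complete_linkage_partition(values, k: int) -> frozenset:
    """Exhaustive furthest-neighbour agglomeration of 1-D points.

    Repeatedly merges the two clusters with the smallest maximum pairwise
    distance (ties by smallest member index) until ``k`` clusters remain.
    Returns a partition as a frozenset of frozensets of point indices.
    """
    values = np.asarray(values, float)
    clusters = [frozenset([i]) for i in range(len(values))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(abs(values[i] - values[j])
                        for i in clusters[a] for j in clusters[b])
                key = (d, min(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return frozenset(clusters)


def partition_of_report(report) -> frozenset:
    """Partition (by row position) induced by a grading report's cluster ids."""
    ids = report.table["cluster_id"].to_numpy()
    return frozenset(frozenset(np.flatnonzero(ids == c)) for c in np.unique(ids))
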
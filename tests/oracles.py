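"""Independent brute-force oracles used by the tests.

These are deliberately naive implementations, written separately from the
package code paths they check.
"""

from __future__ import annotations

import numpy as np


def optimal_1d_kmeans_assignments(values, k):
    """Exhaustive optimal 1-D k-means via a naive quadratic DP.

    Returns cluster labels 1..k (ascending by cluster mean) for each input
    value. Works on the raw (unweighted) value list; optimal 1-D clusterings
    are contiguous in sorted order, so the DP searches all split points.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)

    def sse(i, j):  # cost of x[i:j]
        seg = x[i:j]
        return float(((seg - seg.mean()) ** 2).sum()) if j > i else 0.0

    INF = float("inf")
    cost = [[INF] * (n + 1) for _ in range(k + 1)]
    back = [[0] * (n + 1) for _ in range(k + 1)]
    cost[0][0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, arg = INF, 0
            for i in range(kk - 1, j):
                c = cost[kk - 1][i] + sse(i, j)
                if c < best - 1e-12:
                    best, arg = c, i
            cost[kk][j] = best
            back[kk][j] = arg
    # backtrack cluster boundaries
    bounds = [n]
    j = n
    for kk in range(k, 0, -1):
        j = back[kk][j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for c in range(k):
        labels_sorted[bounds[c] : bounds[c + 1]] = c + 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def exact_svd_mnn_pairs(X1, X2, d=20, k=20):
    """Mutual nearest neighbors from an exact SVD, by exhaustive search."""
    X = np.asarray(X1, dtype=float) @ np.asarray(X2, dtype=float).T
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, V = U[:, :d], Vt[:d].T
    for A in (U, V):
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        A /= norms
    duv = np.linalg.norm(U[:, None, :] - V[None, :, :], axis=2)
    k1 = min(k, V.shape[0])
    k2 = min(k, U.shape[0])
    knn_u = [set(np.argsort(duv[i])[:k1]) for i in range(U.shape[0])]
    knn_v = [set(np.argsort(duv[:, j])[:k2]) for j in range(V.shape[0])]
    pairs = set()
    for i in range(U.shape[0]):
        for j in knn_u[i]:
            if i in knn_v[j]:
                pairs.add((i, int(j)))
    return sorted(pairs)
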
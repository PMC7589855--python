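"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the Ward oracle keeps a
dictionary of cluster pairs and recomputes every Lance-Williams update from
scratch; the k-means oracle enumerates all label assignments; the CA oracle
eigendecomposes the residual cross-product instead of using an SVD.
"""

from itertools import product

import numpy as np
import scipy.linalg


def ward_merge_sequence(d: np.ndarray, dialect: str = "d"):
    """Ward agglomeration by explicit pairwise recomputation.

    Returns a list of (leafset_a, leafset_b, height) in merge order, taking
    the lexicographically first pair (by creation order) on ties.
    """
    n = d.shape[0]
    work = d.astype(float) ** 2 if dialect == "d2" else d.astype(float)
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    dist = {(a, b): work[a, b] for a in range(n) for b in range(a + 1, n)}
    order = {frozenset([i]): i for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                key = (order[a], order[b]) if order[a] < order[b] else (order[b], order[a])
                v = dist[key]
                if best is None or v < best[0]:
                    best = (v, i, j)
        v, i, j = best
        a, b = clusters[i], clusters[j]
        height = float(np.sqrt(v)) if dialect == "d2" else float(v)
        merges.append((a, b, height))
        union = a | b
        sa, sb = len(a), len(b)
        new_id = nxt
        nxt += 1
        for other in clusters:
            if other in (a, b):
                continue
            sx = len(other)
            ka = tuple(sorted((order[a], order[other])))
            kb = tuple(sorted((order[b], order[other])))
            du = ((sa + sx) * dist[ka] + (sb + sx) * dist[kb] - sx * v) / (sa + sb + sx)
            dist[tuple(sorted((new_id, order[other])))] = du
        clusters = [c for c in clusters if c not in (a, b)] + [union]
        order[union] = new_id
    return merges


def kmeans_optimal_wcss(X: np.ndarray, k: int) -> float:
    """Global optimum of the within-cluster sum of squares by enumerating
    every assignment of n points to at most k clusters."""
    n = X.shape[0]
    labels = np.array(list(product(range(k), repeat=n)))
    best = np.inf
    sq = (X**2).sum(axis=1)
    for j in range(k):
        pass  # vectorized below
    wcss = np.zeros(len(labels))
    for j in range(k):
        mask = labels == j
        cnt = mask.sum(axis=1)
        sums = mask @ X
        ss = mask @ sq
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = ss - (sums**2).sum(axis=1) / cnt
        wcss += np.where(cnt > 0, contrib, 0.0)
    return float(wcss.min())


def ca_eigenvalues(indicator: np.ndarray) -> np.ndarray:
    """Correspondence-analysis eigenvalues via a dense symmetric
    eigendecomposition of S S^T (independent of the SVD route)."""
    P = indicator / indicator.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    lam = scipy.linalg.eigh(S @ S.T, eigvals_only=True)[::-1]
    return lam[lam > 1e-12]
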
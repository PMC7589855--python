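"""Hierarchical clustering of variables (and extracts) with Ward linkage on
Pearson-correlation distance.

Two Ward dialects are provided, mirroring the two conventions in common
statistical software:

* ``d``  — the Lance–Williams update applied directly to the dissimilarities
  ``1 - r`` (the historical formulation; default);
* ``d2`` — the update applied to squared dissimilarities with heights
  reported on the original scale (the variance-minimizing formulation,
  equivalent to scipy's ``ward`` on a condensed distance matrix).

Merges are deterministic: on tied heights the pair with the smallest
cluster indices (leaves first, then creation order) is merged first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core_data import LatentVariable, VarSet

__all__ = [
    "DistanceMatrix",
    "VariableTree",
    "HeatmapLayout",
    "pearson_distance",
    "ward_linkage",
    "cut_tree",
    "form_latent",
    "two_way_heatmap",
]

WardDialect = Literal["d", "d2"]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix d = 1 - r over labelled items."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape disagrees with labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < -1e-12):
            raise ValueError("negative dissimilarities")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("non-zero diagonal")


@dataclass
class VariableTree:
    """Agglomerative tree in scipy linkage format over labelled leaves.

    Row ``i`` of ``merges`` is ``(left, right, height, size)``; cluster ids
    ``0..n-1`` are leaves, ``n+i`` is the cluster created by row ``i``.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Depth-first leaf order (left subtree = earlier-created cluster)."""
        n = self.n_leaves
        order: list[int] = []

        def walk(node: int) -> None:
            if node < n:
                order.append(node)
            else:
                left, right = self.merges[node - n, :2]
                walk(int(left))
                walk(int(right))

        walk(2 * n - 2)
        return [self.labels[i] for i in order]


@dataclass
class HeatmapLayout:
    """Two-way seriation: row/column trees and the permuted z-score matrix."""

    row_tree: VariableTree
    col_tree: VariableTree
    row_order: list[str]
    col_order: list[str]
    matrix: pd.DataFrame


def pearson_distance(
    m: pd.DataFrame, axis: Literal["variables", "extracts"] = "variables"
) -> DistanceMatrix:
    """Pairwise ``1 - Pearson r`` between columns (or rows) of ``m``."""
    frame = m if axis == "variables" else m.T
    if frame.shape[1] < 2:
        raise ValueError("need at least two items to compute distances")
    if frame.shape[0] < 2:
        raise ValueError("need at least two observations per item")
    sd = frame.std(ddof=0)
    degenerate = list(sd.index[sd == 0.0])
    if degenerate:
        raise ValueError(f"zero-variance items: {degenerate}")
    r = np.corrcoef(frame.values, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(labels=list(frame.columns), d=d)


def ward_linkage(dist: DistanceMatrix, dialect: WardDialect = "d") -> VariableTree:
    """Agglomerative Ward tree via the Lance–Williams recurrence.

    O(n^3); fine for the tens of variables this workflow clusters.
    """
    if dialect not in ("d", "d2"):
        raise ValueError(f"unknown ward dialect {dialect!r}")
    n = len(dist.labels)
    work = dist.d.astype(float).copy()
    if dialect == "d2":
        work = work**2

    # cluster id -> (row in work, size); rows are compacted as we merge
    ids = list(range(n))
    sizes = {i: 1.0 for i in range(n)}
    cur = work
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        m = len(ids)
        best = np.inf
        pair = (0, 1)
        for a in range(m):
            for b in range(a + 1, m):
                v = cur[a, b]
                # ids are in creation order, so (a, b) position order is the
                # smallest-indices tie-break
                if v < best:
                    best = v
                    pair = (a, b)
        a, b = pair
        ia, ib = ids[a], ids[b]
        sa, sb = sizes[ia], sizes[ib]
        height = float(np.sqrt(max(best, 0.0))) if dialect == "d2" else float(best)
        merges[step] = (ia, ib, height, sa + sb)

        keep = [x for x in range(m) if x not in (a, b)]
        new_row = np.empty(len(keep))
        for j, x in enumerate(keep):
            sx = sizes[ids[x]]
            denom = sa + sb + sx
            new_row[j] = (
                (sa + sx) / denom * cur[a, x]
                + (sb + sx) / denom * cur[b, x]
                - sx / denom * best
            )
        nxt = np.empty((len(keep) + 1, len(keep) + 1))
        nxt[: len(keep), : len(keep)] = cur[np.ix_(keep, keep)]
        nxt[: len(keep), -1] = new_row
        nxt[-1, : len(keep)] = new_row
        nxt[-1, -1] = 0.0
        cur = nxt
        ids = [ids[x] for x in keep] + [next_id]
        sizes[next_id] = sa + sb
        next_id += 1
    return VariableTree(labels=list(dist.labels), merges=merges)


def cut_tree(tree: VariableTree, k: int) -> list[list[str]]:
    """Partition leaves into ``k`` clusters by removing the k-1 last merges.

    Clusters are ordered by their first leaf in input order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _, _ = tree.merges[step]
        new = n + step
        parent[find(int(left))] = new
        parent[find(int(right))] = new

    groups: dict[int, list[str]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(tree.labels[leaf])
    return sorted(groups.values(), key=lambda g: tree.labels.index(g[0]))


def form_latent(
    partition: list[list[str]],
    var_set: VarSet,
    naming: dict[frozenset, tuple[str, int]] | None = None,
) -> list[LatentVariable]:
    """Turn a variable partition into (unassigned) latent variables.

    ``naming`` maps frozenset(members) -> (name, k_levels); clusters not in
    the map get an auto-name from member initials and k_levels=2.
    Singleton clusters are allowed (a latent variable with one member).
    """
    seen: set[str] = set()
    latents = []
    for cluster in partition:
        if not cluster:
            raise ValueError("empty cluster in partition")
        if seen & set(cluster):
            raise ValueError("partition assigns a variable to two clusters")
        seen |= set(cluster)
        key = frozenset(cluster)
        if naming and key in naming:
            name, k = naming[key]
        else:
            name, k = "".join(v[0] for v in cluster), 2
        latents.append(
            LatentVariable(name=name, members=list(cluster), var_set=var_set, k_levels=k)
        )
    return latents


def paper_naming(expected: list[LatentVariable]) -> dict[frozenset, tuple[str, int]]:
    """Naming map (member set -> published name and k) from the reference."""
    return {frozenset(lv.members): (lv.name, lv.k_levels) for lv in expected}


def two_way_heatmap(m: pd.DataFrame, dialect: WardDialect = "d") -> HeatmapLayout:
    """Cluster both extracts and variables; return the seriated matrix."""
    col_tree = ward_linkage(pearson_distance(m, "variables"), dialect)
    row_tree = ward_linkage(pearson_distance(m, "extracts"), dialect)
    row_order = row_tree.leaf_order()
    col_order = col_tree.leaf_order()
    return HeatmapLayout(
        row_tree=row_tree,
        col_tree=col_tree,
        row_order=row_order,
        col_order=col_order,
        matrix=m.loc[row_order, col_order],
    )
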
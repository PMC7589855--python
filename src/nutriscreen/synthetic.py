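"""Synthetic datasets with the structure the screening workflow assumes.

Each variable block shares one latent factor: for extract i and any variable
in block b, value = loading * offset(level of i in b) + noise_sd * eps with
iid standard-normal eps.  Level offsets are expressed in sd units, so a
3-sd gap between planted levels makes the k-means leveling step
unambiguous.  Blocks are mutually independent, extracts carry an
animal/dairy/plant-style origin label, and the planted truth is returned
alongside the table for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core_data import ExtractID, FeatureTable, ORIGINS, VariableDef

__all__ = ["BlockSpec", "SyntheticSpec", "SyntheticTruth", "generate", "score_recovery"]

_DEFAULT_OFFSETS = {2: (-1.5, 1.5), 3: (-3.0, 0.0, 3.0)}


@dataclass
class BlockSpec:
    """One planted variable block."""

    name: str
    n_variables: int
    loading: float = 0.9
    k_levels: int = 2
    offsets: tuple[float, ...] | None = None  # ascending, in sd units
    planted: list[int] | None = None  # per-extract level index, else random

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [0, 1]")
        if self.n_variables < 1:
            raise ValueError("block needs at least one variable")
        if self.offsets is None:
            self.offsets = _DEFAULT_OFFSETS[self.k_levels]
        if len(self.offsets) != self.k_levels:
            raise ValueError("one offset per level required")
        if list(self.offsets) != sorted(self.offsets) or len(set(self.offsets)) < self.k_levels:
            raise ValueError("offsets must be strictly increasing")


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults mirror the study's shape
    (27 extracts in three origin groups, correlated variable blocks)."""

    n_extracts: int = 27
    blocks: list[BlockSpec] = field(default_factory=lambda: [
        BlockSpec("block1", 5), BlockSpec("block2", 4), BlockSpec("block3", 3),
    ])
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(b.n_variables for b in self.blocks) < 2:
            raise ValueError("need at least two variables in total")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")


@dataclass
class SyntheticTruth:
    """Planted structure: variable partition, level assignments, origins."""

    partition: list[list[str]]  # variable names per block
    levels: dict[str, list[int]]  # block name -> per-extract level index
    origins: list[str]

    def partition_labels(self) -> dict[str, int]:
        return {v: b for b, block in enumerate(self.partition) for v in block}


def _codes(n: int) -> list[str]:
    """Extract-style codes cycling A/D/P origins: A1..A9, D1..D9, P1..P9, ..."""
    out = []
    letters = "ADP"
    per = (n + 2) // 3
    for j in range(n):
        out.append(f"{letters[j // per]}{j % per + 1}")
    return out


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw one dataset; deterministic for a fixed spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_extracts
    codes = _codes(n)
    columns: dict[str, np.ndarray] = {}
    partition: list[list[str]] = []
    levels: dict[str, list[int]] = {}
    for block in spec.blocks:
        if block.planted is not None:
            if len(block.planted) != n:
                raise ValueError(f"{block.name}: planted levels must cover all extracts")
            lv = list(block.planted)
        else:
            lv = rng.integers(0, block.k_levels, size=n).tolist()
        levels[block.name] = lv
        common = np.array([block.offsets[i] for i in lv], dtype=float)
        names = [f"{block.name}_v{j + 1}" for j in range(block.n_variables)]
        partition.append(names)
        for name in names:
            eps = rng.standard_normal(n)
            columns[name] = block.loading * common + spec.noise_sd * eps

    frame = pd.DataFrame(columns, index=codes)
    extracts = [ExtractID(code=c, origin=ORIGINS[c[0]]) for c in codes]
    variables = [VariableDef(name=c, unit="z", var_set="composition") for c in frame.columns]
    table = FeatureTable(extracts=extracts, variables=variables, values=frame)
    truth = SyntheticTruth(
        partition=partition, levels=levels, origins=[e.origin for e in extracts]
    )
    return table, truth


def score_recovery(
    truth: SyntheticTruth,
    partition: list[list[str]] | None = None,
    level_assignments: dict[str, list[int]] | None = None,
    axis1_signs: np.ndarray | None = None,
    group_labels: np.ndarray | None = None,
) -> dict:
    """Compare workflow output with the planted truth.

    Returns a dict with ``partition_ari`` (adjusted Rand index between
    planted and recovered variable partitions), per-block ``level_accuracy``
    (after the best level-to-cluster matching for the block's k), and
    ``axis1_separation`` (fraction of extracts whose MCA axis-1 sign agrees
    with the majority sign of their planted group).
    """
    out: dict = {}
    if partition is not None:
        t = truth.partition_labels()
        g = {v: b for b, block in enumerate(partition) for v in block}
        if set(t) != set(g):
            raise ValueError("recovered partition covers a different variable set")
        names = sorted(t)
        out["partition_ari"] = float(
            adjusted_rand_score([t[v] for v in names], [g[v] for v in names])
        )
    if level_assignments is not None:
        accs = {}
        for name, pred in level_assignments.items():
            true = truth.levels[name]
            if len(pred) != len(true):
                raise ValueError(f"{name}: length mismatch")
            k = max(max(true), max(pred)) + 1
            from itertools import permutations

            best = 0.0
            for perm in permutations(range(k)):
                acc = np.mean([perm[p] == t_ for p, t_ in zip(pred, true)])
                best = max(best, float(acc))
            accs[name] = best
        out["level_accuracy"] = accs
    if axis1_signs is not None and group_labels is not None:
        signs = np.sign(axis1_signs)
        agree = []
        for grp in np.unique(group_labels):
            sel = signs[group_labels == grp]
            majority = 1.0 if sel.sum() >= 0 else -1.0
            agree.append((sel == majority).mean())
        out["axis1_separation"] = float(np.mean(agree))
    return out
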
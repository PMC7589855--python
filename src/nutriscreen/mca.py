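"""Multiple correspondence analysis of the H/M/L categorical table.

The categorical table is expanded into a complete disjunctive (indicator)
matrix Z with one 0/1 column per (latent variable, level) category, and a
plain correspondence analysis of Z is computed: chi-square metric on the
row/column profiles, generalized SVD of the standardized residuals,
eigenvalues = squared singular values.  With J categories over Q variables
the total inertia is (J - Q) / Q and at most J - Q axes are non-trivial.
Percent inertia is reported as the raw eigenvalue share (no Benzécri or
Greenacre correction), the convention of FactoMineR-style MCA output.

Latent variables with a near-singleton level (a class of two extracts or
fewer, by default) are excluded beforehand: a tiny category would dominate
the chi-square metric and act as an outlier axis of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CategoricalTable

__all__ = [
    "IndicatorMatrix",
    "MCAResult",
    "filter_latent",
    "build_indicator",
    "mca_fit",
    "mca_summary",
]

_LEVEL_ORDER = ("H", "M", "L")


@dataclass
class IndicatorMatrix:
    """Complete disjunctive coding: rows = extracts, one column per category."""

    frame: pd.DataFrame  # 0/1, columns like "TIVLK=H"
    n_variables: int  # Q

    def __post_init__(self) -> None:
        rs = self.frame.sum(axis=1)
        if not (rs == self.n_variables).all():
            raise ValueError("indicator rows must each sum to the number of variables")
        if (self.frame.sum(axis=0) < 1).any():
            raise ValueError("empty category column")

    @property
    def n_categories(self) -> int:
        return self.frame.shape[1]


@dataclass
class MCAResult:
    """Eigenvalues, inertia shares, and row/category coordinates."""

    eigenvalues: np.ndarray  # descending, non-trivial axes only
    percent_inertia: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame  # extracts x axes (principal coordinates)
    col_coords: pd.DataFrame  # categories x axes (principal coordinates)
    col_contrib: pd.DataFrame  # percent contribution of categories per axis
    col_cos2: pd.DataFrame
    row_masses: pd.Series = field(repr=False, default=None)
    col_masses: pd.Series = field(repr=False, default=None)
    J: int = 0
    Q: int = 0

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def filter_latent(table: CategoricalTable, min_class_size: int = 2) -> CategoricalTable:
    """Drop latent variables having any level with <= min_class_size members."""
    if min_class_size < 0:
        raise ValueError("min_class_size must be >= 0")
    keep = []
    for name in table.latents:
        counts = table.frame[name].value_counts()
        if counts.min() > min_class_size:
            keep.append(name)
    if not keep:
        raise ValueError("exclusion rule dropped every latent variable")
    return CategoricalTable(frame=table.frame[keep].copy())


def dropped_latents(table: CategoricalTable, min_class_size: int = 2) -> list[str]:
    """Names the exclusion rule would remove (for logging/reporting)."""
    kept = set(filter_latent(table, min_class_size).latents)
    return [n for n in table.latents if n not in kept]


def build_indicator(table: CategoricalTable) -> IndicatorMatrix:
    """One 0/1 column per observed (latent, level) pair, H before M before L."""
    cols = {}
    for name in table.latents:
        present = set(table.frame[name])
        for level in _LEVEL_ORDER:
            if level in present:
                cols[f"{name}={level}"] = (table.frame[name] == level).astype(float)
    frame = pd.DataFrame(cols, index=table.frame.index)
    return IndicatorMatrix(frame=frame, n_variables=len(table.latents))


def mca_fit(ind: IndicatorMatrix, n_axes: int | None = None) -> MCAResult:
    """Correspondence analysis of the indicator matrix.

    Axis signs are fixed so the category with the largest contribution on
    each axis has a positive coordinate (CA axes are sign-indeterminate).
    """
    J, Q = ind.n_categories, ind.n_variables
    if J <= Q:
        raise ValueError("need more categories than variables (J > Q)")
    N = ind.frame.values
    if N.shape[0] < 2:
        raise ValueError("need at least two extracts")
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    lam = s**2
    keep = lam > 1e-12
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("degenerate input: all profiles identical")
    if n_axes is not None:
        n_keep = min(n_keep, n_axes)
    U, s, Vt, lam = U[:, :n_keep], s[:n_keep], Vt[:n_keep], lam[:n_keep]

    row_coords = (U * s) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * s) / np.sqrt(c)[:, None]
    contrib = 100.0 * (c[:, None] * col_coords**2) / lam[None, :]

    # deterministic sign: top-contributing category positive on each axis
    for a in range(n_keep):
        lead = int(np.argmax(contrib[:, a]))
        if col_coords[lead, a] < 0:
            col_coords[:, a] *= -1.0
            row_coords[:, a] *= -1.0

    sq_dist = ((P / r[:, None] - c) ** 2 / c).sum(axis=1)  # row profile to centroid
    col_sq_dist = ((P.T / c[:, None] - r) ** 2 / r).sum(axis=1)
    cos2 = col_coords**2 / col_sq_dist[:, None]

    axes = [f"dim{a + 1}" for a in range(n_keep)]
    rows = ind.frame.index
    cats = ind.frame.columns
    total = float((J - Q) / Q)
    return MCAResult(
        eigenvalues=lam,
        percent_inertia=100.0 * lam / total,
        total_inertia=total,
        row_coords=pd.DataFrame(row_coords, index=rows, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=cats, columns=axes),
        col_contrib=pd.DataFrame(contrib, index=cats, columns=axes),
        col_cos2=pd.DataFrame(cos2, index=cats, columns=axes),
        row_masses=pd.Series(r, index=rows),
        col_masses=pd.Series(c, index=cats),
        J=J,
        Q=Q,
    )


def mca_summary(res: MCAResult, dims: int = 2, n_extreme: int = 3) -> dict:
    """Per-axis report: inertia, extreme individuals on each side, and the
    top-contributing categories (the "opposed individuals" reading of the
    factor map)."""
    if dims > res.n_axes:
        raise ValueError(f"dims={dims} exceeds available axes {res.n_axes}")
    report: dict = {"axes": []}
    for a in range(dims):
        axis = f"dim{a + 1}"
        coords = res.row_coords[axis].sort_values()
        report["axes"].append(
            {
                "axis": axis,
                "eigenvalue": float(res.eigenvalues[a]),
                "percent_inertia": float(res.percent_inertia[a]),
                "negative_extremes": list(coords.index[:n_extreme]),
                "positive_extremes": list(coords.index[-n_extreme:][::-1]),
                "top_categories": list(
                    res.col_contrib[axis].sort_values(ascending=False).index[:5]
                ),
            }
        )
    return report
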
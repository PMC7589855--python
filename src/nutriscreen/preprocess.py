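"""Variable-set selection, missing-value policy, and column standardization.

All clustering stages operate on per-column z-scores, so measurement units
(%, ppm, mg/g, ...) never need converting: standardization makes the scales
commensurate.
"""

from __future__ import annotations

from typing import Literal

import pandas as pd

from .core_data import FeatureTable, VarSet

__all__ = ["select_variables", "resolve_missing", "standardize"]

MissingPolicy = Literal["zero", "column_min", "column_mean"]


def select_variables(table: FeatureTable, var_set: VarSet) -> FeatureTable:
    """Slice the table to one variable set, preserving extract order."""
    names = table.variable_names(var_set)
    if not names:
        raise ValueError(f"no variables tagged {var_set!r}")
    return table.slice_variables(names)


def resolve_missing(table: FeatureTable, policy: MissingPolicy = "zero") -> FeatureTable:
    """Replace masked cells so the table is fully numeric.

    ``zero`` treats a not-retrieved analyte as absent / below detection;
    ``column_min`` and ``column_mean`` impute the column statistic over the
    observed cells.
    """
    values = table.values.copy()
    fully_masked = values.columns[values.isna().all()]
    if len(fully_masked):
        raise ValueError(f"columns entirely masked: {list(fully_masked)}")
    if policy == "zero":
        values = values.fillna(0.0)
    elif policy == "column_min":
        values = values.fillna(values.min())
    elif policy == "column_mean":
        values = values.fillna(values.mean())
    else:
        raise ValueError(f"unknown missing policy {policy!r}")
    return FeatureTable(
        extracts=list(table.extracts),
        variables=list(table.variables),
        values=values,
        tokens={},
    )


def standardize(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores with the sample (n-1) standard deviation.

    Raises on masked cells or zero-variance columns (named in the error):
    a constant column carries no ordering information and would divide by
    zero.
    """
    frame = table.values if isinstance(table, FeatureTable) else table
    if frame.isna().any().any():
        bad = list(frame.columns[frame.isna().any()])
        raise ValueError(f"masked cells remain in columns {bad}; resolve_missing first")
    sd = frame.std(ddof=1)
    constant = list(sd.index[sd == 0.0])
    if constant:
        raise ValueError(f"zero-variance columns: {constant}")
    return (frame - frame.mean()) / sd
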
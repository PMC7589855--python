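"""End-to-end orchestration: config -> preprocess -> variable clustering ->
leveling -> small-class filter -> MCA -> screening report.

Every intermediate (standardized matrices, trees, partitions, level tables,
MCA coordinates) is persisted under the output directory so any stage can
be audited or rerun; the value of the workflow is the auditable chain, not
a single number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hcluster, leveling, mca, preprocess
from .core_data import CategoricalTable, FeatureTable, LatentVariable, paper_fixture

__all__ = ["WorkflowConfig", "ScreeningReport", "run_workflow", "profile_of_group"]

log = logging.getLogger("nutriscreen")

VAR_SETS = ("composition", "gastric", "intestinal")


@dataclass
class WorkflowConfig:
    """Configuration of a full screening run.

    ``inputs`` maps variable-set name -> file path, or is None to use the
    packaged study dataset, in which case the published
    latent-variable names and level counts are applied to matching clusters.
    """

    inputs: dict[str, str] | None = None
    missing_policy: preprocess.MissingPolicy = "zero"
    ward_dialect: hcluster.WardDialect = "d"
    cluster_counts: dict[str, int] = field(
        default_factory=lambda: {"composition": 9, "gastric": 3, "intestinal": 3}
    )
    k_map: dict[str, int] | None = None  # latent name -> levels, overrides defaults
    seed: int = leveling.DEFAULT_SEED
    restarts: int = leveling.DEFAULT_RESTARTS
    min_class_size: int = 2
    mca_dims: int = 5
    center_deadzone: float = 0.25
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        for name, k in self.cluster_counts.items():
            if k < 1:
                raise ValueError(f"cluster count for {name!r} must be >= 1")


@dataclass
class ScreeningReport:
    """Everything the screening run produced."""

    latents: list[LatentVariable]
    categorical: CategoricalTable
    dropped: list[str]
    mca_result: mca.MCAResult
    summary: dict
    quadrants: pd.DataFrame  # per extract: dim1, dim2, quadrant label

    def level_table(self) -> pd.DataFrame:
        """Level matrix in the style of the published summary table."""
        rows = []
        for lv in self.latents:
            rows.append(
                {
                    "latent": lv.name,
                    "var_set": lv.var_set,
                    "k": lv.k_levels,
                    "members": ";".join(lv.members),
                    "high": ";".join(lv.level_members("H")),
                    "medium": ";".join(lv.level_members("M")),
                    "low": ";".join(lv.level_members("L")),
                }
            )
        return pd.DataFrame(rows)


def _quadrants(res: mca.MCAResult, deadzone: float) -> pd.DataFrame:
    coords = res.row_coords[["dim1", "dim2"]].copy()
    labels = []
    for _, row in coords.iterrows():
        if abs(row.dim1) < deadzone and abs(row.dim2) < deadzone:
            labels.append("center")
        else:
            labels.append(("+" if row.dim1 >= 0 else "-") + ("+" if row.dim2 >= 0 else "-"))
    coords["quadrant"] = labels
    return coords


def run_workflow(cfg: WorkflowConfig) -> ScreeningReport:
    """Execute all stages in order, persisting intermediates if requested."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    if cfg.inputs is None:
        table, _meta, expected = paper_fixture()
        naming = hcluster.paper_naming(expected)
    else:
        from .core_data import load_feature_table

        parts = [
            load_feature_table(cfg.inputs[vs], vs)  # type: ignore[arg-type]
            for vs in VAR_SETS
            if vs in cfg.inputs
        ]
        table = parts[0]
        for p in parts[1:]:
            table = table.hstack(p)
        naming = None

    latents: list[LatentVariable] = []
    z_all: list[pd.DataFrame] = []
    for vs in VAR_SETS:
        names = table.variable_names(vs)
        if not names:
            continue
        sel = preprocess.select_variables(table, vs)  # type: ignore[arg-type]
        sel = preprocess.resolve_missing(sel, cfg.missing_policy)
        z = preprocess.standardize(sel)
        z_all.append(z)
        tree = hcluster.ward_linkage(hcluster.pearson_distance(z), cfg.ward_dialect)
        k = cfg.cluster_counts.get(vs, 3)
        partition = hcluster.cut_tree(tree, k)
        latents += hcluster.form_latent(partition, vs, naming)  # type: ignore[arg-type]
        log.info("%s: %d variables -> %d clusters", vs, len(names), k)
        if out:
            z.to_csv(out / f"zscores_{vs}.csv")
            (out / f"tree_{vs}.json").write_text(
                json.dumps({"labels": tree.labels, "merges": tree.merges.tolist()}, indent=1)
            )

    z_full = pd.concat(z_all, axis=1)
    latents, _models = leveling.assign_levels(
        latents, z_full, cfg.k_map, cfg.seed, cfg.restarts
    )
    cat = leveling.build_categorical_table(latents)
    dropped = mca.dropped_latents(cat, cfg.min_class_size)
    retained = mca.filter_latent(cat, cfg.min_class_size)
    if dropped:
        log.info("excluded by small-class rule: %s", ", ".join(dropped))

    res = mca.mca_fit(mca.build_indicator(retained))
    dims = min(cfg.mca_dims, res.n_axes)
    summary = mca.mca_summary(res, dims=min(2, dims))
    quadrants = _quadrants(res, cfg.center_deadzone)

    report = ScreeningReport(
        latents=latents,
        categorical=retained,
        dropped=dropped,
        mca_result=res,
        summary=summary,
        quadrants=quadrants,
    )
    if out:
        report.level_table().to_csv(out / "levels.csv", index=False)
        cat.frame.to_csv(out / "categorical_full.csv")
        retained.frame.to_csv(out / "categorical_retained.csv")
        eigen = pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues,
                "percent_inertia": res.percent_inertia,
            },
            index=[f"dim{i + 1}" for i in range(res.n_axes)],
        )
        eigen.to_csv(out / "eigen.csv")
        res.row_coords.iloc[:, :dims].to_csv(out / "ind_coords.csv")
        res.col_coords.iloc[:, :dims].to_csv(out / "cat_coords.csv")
        res.col_contrib.iloc[:, :dims].to_csv(out / "contrib.csv")
        quadrants.to_csv(out / "quadrants.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return report


def profile_of_group(report: ScreeningReport, codes: list[str]) -> pd.DataFrame:
    """Majority level per retained latent variable over a group of extracts.

    One row per latent with the majority level and whether the group is
    unanimous; the shared profile behind a factor-map grouping.
    """
    if not codes:
        raise ValueError("empty group")
    frame = report.categorical.frame
    missing = [c for c in codes if c not in frame.index]
    if missing:
        raise KeyError(f"unknown extracts: {missing}")
    rows = []
    for latent in frame.columns:
        sub = frame.loc[codes, latent]
        counts = sub.value_counts()
        top = counts.index[0]
        rows.append(
            {
                "latent": latent,
                "majority_level": top,
                "unanimous": bool(counts.iloc[0] == len(codes)),
            }
        )
    return pd.DataFrame(rows).set_index("latent")
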
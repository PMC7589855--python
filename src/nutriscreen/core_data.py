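"""Domain types, packaged study data, and delimited-text I/O.

The study dataset covers 27 protein extracts (9 animal ``A1``-``A9``,
9 dairy ``D1``-``D9``, 9 plant ``P1``-``P9``) measured on three variable
sets: proximate/micronutrient composition plus the aminogram (34 active
variables), and bioaccessibility/bioactivity of the gastric and intestinal
digestates (7 variables each).  Dry matter and the two aminogram totals are
carried along but excluded from clustering.

Missing measurements are encoded as ``n.r.`` (not retrieved) or ``NA`` in
the source tables; both are parsed into a mask, with the original token
kept for provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ORIGINS",
    "MISSING_TOKENS",
    "ExtractID",
    "VariableDef",
    "FeatureTable",
    "LatentVariable",
    "CategoricalTable",
    "load_feature_table",
    "write_feature_table",
    "load_metadata",
    "load_expected_latents",
    "paper_fixture",
]

Origin = Literal["animal", "dairy", "plant"]
VarSet = Literal["composition", "gastric", "intestinal", "excluded"]
Level = Literal["H", "M", "L"]

ORIGINS: dict[str, Origin] = {"A": "animal", "D": "dairy", "P": "plant"}
MISSING_TOKENS = ("n.r.", "NA")
_CODE_RE = re.compile(r"^[ADP][1-9]$")

#: Columns of the packaged composition file that never enter clustering:
#: dry matter and the two aminogram totals are derived/bookkeeping columns
#: and are not members of any latent variable.
EXCLUDED_VARIABLES = ("DM", "IAA_TotalAA", "TotalAA")


@dataclass(frozen=True)
class ExtractID:
    """A protein extract: short code, origin group, free-text description."""

    code: str
    origin: Origin
    description: str = ""

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise ValueError(f"bad extract code {self.code!r}: expected [ADP][1-9]")
        expected = ORIGINS[self.code[0]]
        if self.origin != expected:
            raise ValueError(
                f"origin {self.origin!r} inconsistent with code {self.code!r} "
                f"(expected {expected!r})"
            )


@dataclass(frozen=True)
class VariableDef:
    """A measured variable: name, unit, and which variable set it belongs to."""

    name: str
    unit: str = ""
    var_set: VarSet = "composition"


@dataclass
class FeatureTable:
    """Extracts x variables table of quantitative measurements.

    ``values`` holds floats with NaN at masked cells; ``mask`` is True where
    the source printed a missing token, and ``tokens`` remembers which one.
    """

    extracts: list[ExtractID]
    variables: list[VariableDef]
    values: pd.DataFrame  # index = codes, columns = variable names, float
    tokens: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [e.code for e in self.extracts]
        names = [v.name for v in self.variables]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate extract codes")
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if list(self.values.index) != codes or list(self.values.columns) != names:
            raise ValueError("values frame labels disagree with extract/variable lists")

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.extracts]

    def variable_names(self, var_set: VarSet | None = None) -> list[str]:
        return [v.name for v in self.variables if var_set is None or v.var_set == var_set]

    def slice_variables(self, names: list[str]) -> "FeatureTable":
        defs = {v.name: v for v in self.variables}
        missing = [n for n in names if n not in defs]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        return FeatureTable(
            extracts=list(self.extracts),
            variables=[defs[n] for n in names],
            values=self.values[names].copy(),
            tokens={k: t for k, t in self.tokens.items() if k[1] in names},
        )

    def hstack(self, other: "FeatureTable") -> "FeatureTable":
        if [e.code for e in self.extracts] != [e.code for e in other.extracts]:
            raise ValueError("extract rows differ; tables cannot be joined")
        return FeatureTable(
            extracts=list(self.extracts),
            variables=list(self.variables) + list(other.variables),
            values=pd.concat([self.values, other.values], axis=1),
            tokens={**self.tokens, **other.tokens},
        )


@dataclass
class LatentVariable:
    """A named block of correlated variables with ordered level assignments.

    ``assignment`` maps extract code -> level in {H, M, L}; it is empty until
    the leveling stage runs (or when carrying the published reference
    assignments).
    """

    name: str
    members: list[str]
    var_set: VarSet
    k_levels: int = 2
    assignment: dict[str, Level] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"latent variable {self.name!r} has no members")
        if self.k_levels not in (2, 3):
            raise ValueError(f"k_levels must be 2 or 3, got {self.k_levels}")
        if self.k_levels == 2 and "M" in self.assignment.values():
            raise ValueError(f"{self.name!r}: level M assigned but k_levels=2")

    def level_members(self, level: Level) -> list[str]:
        return sorted(c for c, lv in self.assignment.items() if lv == level)


@dataclass
class CategoricalTable:
    """Extracts x latent variables, one H/M/L label per cell."""

    frame: pd.DataFrame  # index = codes, columns = latent names, values H/M/L

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("categorical table contains missing labels")
        bad = set(np.unique(self.frame.values)) - {"H", "M", "L"}
        if bad:
            raise ValueError(f"unknown level labels: {sorted(bad)}")

    @property
    def latents(self) -> list[str]:
        return list(self.frame.columns)

    def levels_of(self, latent: str) -> list[str]:
        present = set(self.frame[latent])
        return [lv for lv in ("H", "M", "L") if lv in present]


# ---------------------------------------------------------------------------
# I/O


def _data_path(name: str) -> Path:
    return Path(str(resources.files("nutriscreen").joinpath("data", name)))


def load_feature_table(
    path: str | Path,
    schema: dict[str, VarSet] | VarSet | None = None,
    units: dict[str, str] | None = None,
    sep: str | None = None,
) -> FeatureTable:
    """Read a delimited text table (header row, first column extract codes).

    ``schema`` maps variable name -> variable set, or is a single set tag
    applied to every column.  Cells equal to ``n.r.`` or ``NA`` are masked.
    """
    path = Path(path)
    if sep is None:
        head = path.read_text().splitlines()[0]
        sep = "\t" if "\t" in head else ","
    header = path.read_text().splitlines()[0].split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({n for n in header if header.count(n) > 1})
        raise ValueError(f"duplicated variable names: {dupes}")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    code_col = raw.columns[0]
    codes = raw[code_col].tolist()
    names = list(raw.columns[1:])
    extracts = []
    for code in codes:
        if not isinstance(code, str) or not _CODE_RE.match(code):
            raise ValueError(f"unknown extract code {code!r}")
        extracts.append(ExtractID(code=code, origin=ORIGINS[code[0]]))

    units = units or {}
    if schema is None or isinstance(schema, str):
        tag: VarSet = schema or "composition"
        variables = [VariableDef(n, units.get(n, ""), tag) for n in names]
    else:
        variables = [
            VariableDef(n, units.get(n, ""), schema.get(n, "composition")) for n in names
        ]

    tokens: dict[tuple[str, str], str] = {}
    data = np.empty((len(codes), len(names)))
    for j, name in enumerate(names):
        for i, cell in enumerate(raw[name]):
            cell = cell.strip() if isinstance(cell, str) else cell
            if cell in MISSING_TOKENS:
                data[i, j] = np.nan
                tokens[(codes[i], name)] = cell
            else:
                try:
                    data[i, j] = float(str(cell).replace(",", ""))
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell {cell!r} at ({codes[i]}, {name})"
                    ) from None
    frame = pd.DataFrame(data, index=codes, columns=names)
    return FeatureTable(extracts=extracts, variables=variables, values=frame, tokens=tokens)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    """Write a table back to delimited text, restoring the missing tokens."""
    out = table.values.astype(object).copy()
    for (code, name), tok in table.tokens.items():
        out.loc[code, name] = tok
    out = out.where(~out.isna(), "NA")
    out.index.name = "code"
    out.to_csv(path, sep=sep)


def load_metadata(path: str | Path | None = None) -> list[ExtractID]:
    """Read extract metadata (code, origin, description)."""
    frame = pd.read_csv(path or _data_path("table1_meta.csv"))
    return [
        ExtractID(code=r.code, origin=r.origin, description=r.description)
        for r in frame.itertuples()
    ]


def load_expected_latents(path: str | Path | None = None) -> list[LatentVariable]:
    """Read the published latent-variable reference (members, k, level lists)."""
    frame = pd.read_csv(path or _data_path("table6_expected.csv")).fillna("")
    latents = []
    for r in frame.itertuples():
        assignment: dict[str, Level] = {}
        for lv, col in (("H", r.high), ("M", r.medium), ("L", r.low)):
            for code in str(col).split(";"):
                if code:
                    assignment[code] = lv  # type: ignore[assignment]
        latents.append(
            LatentVariable(
                name=r.latent,
                members=r.members.split(";"),
                var_set=r.var_set,
                k_levels=int(r.k),
                assignment=assignment,
            )
        )
    return latents


_UNITS = {
    "DM": "%", "Protein": "%", "TotalSugar": "%", "SimpleCarb": "%",
    "ComplexCarb": "%", "Cr": "ppm", "Cu": "ppm", "Zn": "ppm", "Fe": "ppm",
    "Na": "ppm", "Mg": "ppm", "K": "ppm", "Ca": "ppm", "VitC": "mg/g",
    "VitA": "µg/g", "TBARS": "mg MDA/kg", "Carbonyls": "nM hydrazone/mg",
    "IAA_TotalAA": "%", "TotalAA": "%DM",
}
_AMINO = ("His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val",
          "Arg", "Ala", "Asp", "Cys", "Glu", "Gly", "Pro", "Ser", "Tyr")
_DIGEST_UNITS = {
    "Biuret": "mg/g powder",
    "DirectDetect": "mg/g powder",
    "FreeNH2": "mM glycine eq/g",
    "ABTS": "% inhibition",
    "FRAP": "% inhibition",
    "DPPH": "% inhibition",
    "ORAC": "µmol Trolox eq/mg",
}


def paper_fixture() -> tuple[FeatureTable, list[ExtractID], list[LatentVariable]]:
    """The packaged 27-extract study dataset.

    Returns the joined feature table (composition + gastric + intestinal,
    51 columns of which 48 are active), the extract metadata, and the
    published latent-variable assignments used as the regression reference.
    """
    units = dict(_UNITS)
    units.update({a: "%DM" for a in _AMINO})
    schema: dict[str, VarSet] = {n: "excluded" for n in EXCLUDED_VARIABLES}
    comp = load_feature_table(_data_path("table2_3_composition.csv"), schema, units)

    for phase, fname in (("gastric", "table4_gastric.csv"), ("intestinal", "table5_intestinal.csv")):
        u = {f"{k}_{phase[0].upper()}": v for k, v in _DIGEST_UNITS.items()}
        part = load_feature_table(_data_path(fname), phase, u)  # type: ignore[arg-type]
        comp = comp.hstack(part)

    meta = load_metadata()
    by_code = {m.code: m for m in meta}
    comp.extracts = [by_code[e.code] for e in comp.extracts]
    return comp, meta, load_expected_latents()
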
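"""Data model, CSV I/O, validation and region-level aggregation.

The universal input of the pipeline is a :class:`MeasurementTable`: one row
per biological replicate, with a region code, a species label and a set of
named non-negative measurements.  Variables are grouped into
:class:`VariablePanel` objects (e.g. the mineral-element panel or the
quality-indicator panel) that downstream stages operate on.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

META_COLUMNS = ("sample_id", "region", "species")

#: header pattern "name (unit)"
_UNIT_RE = re.compile(r"^\s*(?P<name>.+?)\s*\((?P<unit>[^()]*)\)\s*$")

MINERAL_VARIABLES = ("K", "Ca", "Zn", "Mg", "Cu", "Fe", "Se", "Mn")
QUALITY_VARIABLES = (
    "total_polysaccharide",
    "total_acid",
    "sugar_acid_ratio",
    "total_polyphenols",
    "l_malic_acid",
    "aa2bg",
)

#: units are opaque labels; no conversion is ever attempted
DEFAULT_UNITS: dict[str, str] = {
    "K": "g/kg",
    "Ca": "g/kg",
    "Zn": "ug/kg",
    "Mg": "ug/kg",
    "Cu": "ug/kg",
    "Fe": "ug/kg",
    "Se": "ug/kg",
    "Mn": "ug/kg",
    "total_polysaccharide": "%",
    "total_acid": "%",
    "sugar_acid_ratio": "",
    "total_polyphenols": "%",
    "l_malic_acid": "%",
    "aa2bg": "%",
}


@dataclass(frozen=True)
class VariablePanel:
    """An ordered, named group of variables with a declared role."""

    name: str
    members: tuple[str, ...]
    role: str = "quality"

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if len(set(members)) != len(members):
            raise ValidationError(f"panel {self.name!r} has duplicate members")
        if not members:
            raise ValidationError(f"panel {self.name!r} is empty")
        if self.role not in ("mineral", "quality"):
            raise ValidationError(f"unknown panel role {self.role!r}")

    def check_against(self, table: "MeasurementTable") -> None:
        missing = [m for m in self.members if m not in table.variables]
        if missing:
            raise ValidationError(
                f"panel {self.name!r}: variables not in table: {missing}"
            )


def mineral_panel() -> VariablePanel:
    return VariablePanel("minerals", MINERAL_VARIABLES, role="mineral")


def quality_panel() -> VariablePanel:
    return VariablePanel("quality", QUALITY_VARIABLES, role="quality")


def default_panels() -> list[VariablePanel]:
    return [mineral_panel(), quality_panel()]


@dataclass
class MeasurementTable:
    """Replicate-level observations of regions x variables.

    ``data`` holds one row per sample with columns ``sample_id``, ``region``,
    ``species`` followed by one numeric column per variable.  ``units`` maps
    each variable to an opaque unit label ("" = dimensionless).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- views ---------------------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.data["region"]:
            seen.setdefault(r)
        return list(seen)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def values(self, variables: Iterable[str] | VariablePanel) -> pd.DataFrame:
        if isinstance(variables, VariablePanel):
            variables.check_against(self)
            variables = variables.members
        return self.data.loc[:, list(variables)]

    def replicate_counts(self) -> pd.Series:
        return self.data.groupby("region", sort=False).size()

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for col in META_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(df) == 0:
            raise ValidationError("table has no rows")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if df["region"].isna().any() or (df["region"].astype(str) == "").any():
            raise ValidationError("every row must have a region")
        if df["species"].isna().any():
            raise ValidationError("every row must have a species")
        for var in self.variables:
            col = df[var]
            if not pd.api.types.is_numeric_dtype(col):
                raise ValidationError(f"variable {var!r} is not numeric")
            finite = col.dropna()
            if (finite < 0).any():
                raise ValidationError(f"variable {var!r} has negative values")
            if self.units.get(var) == "%" and (finite > 100).any():
                raise ValidationError(f"percentage variable {var!r} exceeds 100")

    def require_complete(self, variables: Iterable[str], stage: str) -> None:
        """Abort with a named-variable error if any cell needed by *stage* is missing."""
        for var in variables:
            if self.data[var].isna().any():
                raise ValidationError(
                    f"stage {stage!r} requires complete data but variable "
                    f"{var!r} has missing values"
                )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _split_unit_header(header: str) -> tuple[str, str | None]:
    m = _UNIT_RE.match(header)
    if m:
        return m.group("name"), m.group("unit")
    return header.strip(), None


def read_measurements(
    path: str | Path,
    schema: Iterable[VariablePanel] | None = None,
) -> MeasurementTable:
    """Read a wide-format measurement CSV.

    The first row is a header naming ``sample_id`` (optional), ``region``,
    ``species`` and the variables; units may be embedded as ``"name (unit)"``.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty file: {path}") from None

    units: dict[str, str] = {}
    renames: dict[str, str] = {}
    for col in raw.columns:
        name, unit = _split_unit_header(col)
        renames[col] = name
        if unit is not None and name not in META_COLUMNS:
            units[name] = unit
    raw = raw.rename(columns=renames)

    for col in ("region", "species"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "sample_id" not in raw.columns:
        raw.insert(0, "sample_id", [f"S{i + 1}" for i in range(len(raw))])

    variables = [c for c in raw.columns if c not in META_COLUMNS]
    if schema is not None:
        for panel in schema:
            missing = [m for m in panel.members if m not in variables]
            if missing:
                raise SchemaError(
                    f"panel {panel.name!r}: missing column(s) {missing}"
                )

    parsed = raw.copy()
    for var in variables:
        def _parse(cell: object, _var: str = var) -> float:
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                return np.nan
            text = str(cell).strip()
            if text == "":
                return np.nan
            try:
                return float(text)
            except ValueError:
                row = raw.index[raw[_var] == cell][0]
                raise ParseError(
                    f"non-numeric value {text!r} in column {_var!r}, row {row + 2}"
                ) from None

        parsed[var] = raw[var].map(_parse).astype(float)

    for var in variables:
        units.setdefault(var, DEFAULT_UNITS.get(var, ""))
    return MeasurementTable(parsed, units=units)


def write_table(table: MeasurementTable | pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV; units are embedded back into the headers.

    Round-trip property: ``read_measurements(write_table(t))`` reproduces the
    numeric values exactly (Python ``repr`` floats round-trip).
    """
    path = Path(path)
    if isinstance(table, MeasurementTable):
        df = table.data.copy()
        headers = {
            var: f"{var} ({unit})"
            for var, unit in table.units.items()
            if unit and var in df.columns
        }
        df = df.rename(columns=headers)
    else:
        df = table
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_regions(
    table: MeasurementTable, statistic: str = "mean"
) -> MeasurementTable:
    """Collapse replicates to one row per region.

    Species is carried through when unanimous within a region, otherwise the
    region is flagged and its species set to ``"mixed"``.  Idempotent on an
    already-aggregated table.
    """
    if statistic != "mean":
        raise ValueError(f"unsupported statistic {statistic!r}")
    df = table.data
    rows = []
    for region in table.regions:
        sub = df[df["region"] == region]
        species = sub["species"].unique()
        if len(species) > 1:
            warnings.warn(
                f"region {region!r} mixes species {sorted(species)}; "
                'set to "mixed"',
                stacklevel=2,
            )
            sp = "mixed"
        else:
            sp = species[0]
        row: dict[str, object] = {"sample_id": region, "region": region, "species": sp}
        for var in table.variables:
            row[var] = sub[var].mean()
        rows.append(row)
    out = pd.DataFrame(rows, columns=["sample_id", "region", "species", *table.variables])
    return MeasurementTable(out, units=dict(table.units))
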
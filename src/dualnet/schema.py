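"""Cohort table loading, schema validation, value screening, and
complete-case filtering.

A cohort is a rectangular participant x variable table.  Each column is
declared in a :class:`VariableSchema`: its role (continuous / ordinal /
categorical), an optional admissible range, whether it is exempt from
discretization, and whether it may receive incoming arcs during structure
search (sink-forbidden variables form the default blacklist).

Cleaning is two-stage, mirroring a value-then-row accounting:

1. ``apply_screens`` nulls individual offending cells (value removal),
2. ``complete_cases`` drops any row still containing a missing cell.

Both stages log every removal in an :class:`ExclusionLog` whose arithmetic
always reconciles (n_in = n_out + rows dropped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSchema",
    "ScreeningRule",
    "CohortTable",
    "ExclusionLog",
    "load_cohort",
    "load_schema",
    "apply_screens",
    "complete_cases",
]

Role = Literal["continuous", "ordinal", "categorical"]

#: default tokens treated as missing in CSV input
NA_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null", "None")


class SchemaError(ValueError):
    """Raised when a schema declaration or a table violates its contract."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one cohort variable.

    Parameters
    ----------
    name:
        Column identifier; must match the CSV header.
    role:
        ``continuous``, ``ordinal``, or ``categorical``.
    admissible_range:
        Optional closed interval ``(lo, hi)``; after screening every
        non-missing cell must lie inside it.
    ordinal_levels:
        Ordered label list, required for ordinal/categorical roles and
        forbidden for continuous ones.  Labels are encoded to integer
        codes ``1..L`` in declared order.
    discretization_exempt:
        If true the variable passes through discretization untouched.
    blacklist_sink_forbidden:
        If true no arc may point *into* this variable during structure
        search.
    """

    name: str
    role: Role = "continuous"
    admissible_range: tuple[float, float] | None = None
    ordinal_levels: tuple[str, ...] | None = None
    discretization_exempt: bool = False
    blacklist_sink_forbidden: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("continuous", "ordinal", "categorical"):
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "continuous" and self.ordinal_levels is not None:
            raise SchemaError(f"{self.name}: continuous role forbids ordinal_levels")
        if self.role in ("ordinal", "categorical") and not self.ordinal_levels:
            raise SchemaError(f"{self.name}: role {self.role} requires ordinal_levels")
        if self.admissible_range is not None:
            lo, hi = self.admissible_range
            if not lo < hi:
                raise SchemaError(
                    f"{self.name}: admissible_range lower {lo} must be < upper {hi}"
                )
        if self.ordinal_levels is not None:
            if len(set(self.ordinal_levels)) != len(self.ordinal_levels):
                raise SchemaError(f"{self.name}: duplicate ordinal level labels")

    @property
    def level_codes(self) -> dict[str, int] | None:
        """Label -> integer code mapping (1-based, schema order)."""
        if self.ordinal_levels is None:
            return None
        return {lab: i + 1 for i, lab in enumerate(self.ordinal_levels)}


@dataclass(frozen=True)
class ScreeningRule:
    """A value screen: cells of `variable` satisfying the predicate are
    nulled.  Predicates: ``less_than`` (< threshold), ``greater_than``
    (> threshold), ``at_least`` (>= threshold)."""

    variable: str
    predicate: Literal["less_than", "greater_than", "at_least"]
    threshold: float

    def __post_init__(self) -> None:
        if self.predicate not in ("less_than", "greater_than", "at_least"):
            raise SchemaError(f"unknown predicate {self.predicate!r}")
        if not np.isfinite(self.threshold):
            raise SchemaError(f"{self.variable}: screening threshold must be finite")

    def offends(self, values: pd.Series) -> pd.Series:
        """Boolean mask of offending (non-missing) cells."""
        if self.predicate == "less_than":
            mask = values < self.threshold
        elif self.predicate == "greater_than":
            mask = values > self.threshold
        else:
            mask = values >= self.threshold
        return mask.fillna(False)


@dataclass
class ExclusionLog:
    """Accounting of removed values and rows."""

    removed_values: list[dict] = field(default_factory=list)
    removed_rows_incomplete: list = field(default_factory=list)
    n_initial: int = 0
    n_final: int = 0

    @property
    def counts(self) -> dict[str, int]:
        by_var: dict[str, int] = {}
        for rec in self.removed_values:
            by_var[rec["variable"]] = by_var.get(rec["variable"], 0) + 1
        return {
            "values_removed": len(self.removed_values),
            "values_removed_by_variable": by_var,  # type: ignore[dict-item]
            "rows_removed_incomplete": len(self.removed_rows_incomplete),
        }

    def validate(self) -> None:
        if self.n_initial != self.n_final + len(self.removed_rows_incomplete):
            raise AssertionError(
                "exclusion log does not reconcile: "
                f"{self.n_initial} != {self.n_final} + {len(self.removed_rows_incomplete)}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_initial": self.n_initial,
                "n_final": self.n_final,
                "removed_values": self.removed_values,
                "removed_rows_incomplete": list(self.removed_rows_incomplete),
                "counts": self.counts,
            },
            indent=2,
            default=str,
        )


class CohortTable:
    """A validated participant x variable table plus its schema.

    Values are held in a :class:`pandas.DataFrame` with float columns
    (ordinal/categorical labels mapped to 1-based integer codes stored as
    floats so missingness is representable).  Column order follows the
    schema and is stable.
    """

    def __init__(self, data: pd.DataFrame, schema: Sequence[VariableSchema]):
        names = [v.name for v in schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        missing = set(names) - set(data.columns)
        if missing:
            raise SchemaError(f"schema variables absent from data: {sorted(missing)}")
        extra = set(data.columns) - set(names)
        if extra:
            raise SchemaError(f"data columns absent from schema: {sorted(extra)}")
        self.data = data.loc[:, names].copy()
        self.schema = list(schema)
        self._by_name = {v.name: v for v in self.schema}

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.schema)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def variable(self, name: str) -> VariableSchema:
        return self._by_name[name]

    @property
    def sink_forbidden(self) -> list[str]:
        return [v.name for v in self.schema if v.blacklist_sink_forbidden]

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.schema)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def check_ranges(self) -> None:
        """Assert every non-missing cell of a range-constrained variable
        lies in its admissible range."""
        for v in self.schema:
            if v.admissible_range is None:
                continue
            lo, hi = v.admissible_range
            col = self.data[v.name].dropna()
            bad = col[(col < lo) | (col > hi)]
            if len(bad):
                raise SchemaError(
                    f"{v.name}: {len(bad)} value(s) outside admissible range "
                    f"[{lo}, {hi}] (first: {bad.iloc[0]})"
                )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading


def _parse_column(raw: pd.Series, var: VariableSchema) -> pd.Series:
    """Parse one raw string/numeric column per its declared role."""
    as_str = raw.astype("string").str.strip()
    is_na = as_str.isna() | as_str.isin(NA_TOKENS)
    if var.role == "continuous":
        out = pd.to_numeric(as_str.where(~is_na), errors="coerce")
        bad = (~is_na) & out.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {var.name!r}: unparseable numeric cell "
                f"{raw.iloc[row]!r} at row {row}"
            )
        return out.astype(float)
    codes = var.level_codes
    assert codes is not None
    mapped = as_str.where(~is_na).map(codes)
    # labels may already be the integer codes themselves
    numeric = pd.to_numeric(as_str.where(~is_na), errors="coerce")
    valid_codes = set(codes.values())
    numeric = numeric.where(numeric.isin(list(valid_codes)))
    out = mapped.astype(float).fillna(numeric.astype(float))
    bad = (~is_na) & out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"column {var.name!r}: label {raw.iloc[row]!r} at row {row} not in "
            f"declared levels {list(codes)}"
        )
    return out


def load_cohort(csv_path: str | Path, schema: Sequence[VariableSchema]) -> CohortTable:
    """Read a cohort CSV and validate it against `schema`.

    The header must match the schema names (order-insensitive); ordinal and
    categorical labels are mapped to 1-based integer codes in declared
    order.  Unknown columns, duplicate columns, or unparseable cells raise
    :class:`SchemaError` naming the offender.
    """
    import csv as _csv

    with open(csv_path, newline="") as fh:
        header = next(_csv.reader(fh))
    header = [h.strip() for h in header]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise SchemaError(f"duplicate column(s) in CSV: {dups}")
    raw = pd.read_csv(csv_path, dtype=str, keep_default_na=False, skipinitialspace=True)
    names = {v.name for v in schema}
    unknown = [c for c in raw.columns if c not in names]
    if unknown:
        raise SchemaError(f"CSV column(s) not declared in schema: {unknown}")
    absent = [n for n in names if n not in raw.columns]
    if absent:
        raise SchemaError(f"schema variable(s) missing from CSV: {sorted(absent)}")
    parsed = {v.name: _parse_column(raw[v.name], v) for v in schema}
    return CohortTable(pd.DataFrame(parsed), schema)


def load_schema(path: str | Path) -> tuple[list[VariableSchema], list[ScreeningRule]]:
    """Load a YAML/JSON schema config.

    Expected layout::

        variables:
          - name: bmi
            role: continuous
            admissible_range: [13, 90]
          - name: gender
            role: categorical
            ordinal_levels: [women, men]
            discretization_exempt: true
            blacklist_sink_forbidden: true
        screens:
          - {variable: bmi, predicate: less_than, threshold: 13}
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    variables = []
    for entry in cfg.get("variables", []):
        entry = dict(entry)
        if "admissible_range" in entry and entry["admissible_range"] is not None:
            entry["admissible_range"] = tuple(entry["admissible_range"])
        if "ordinal_levels" in entry and entry["ordinal_levels"] is not None:
            entry["ordinal_levels"] = tuple(str(x) for x in entry["ordinal_levels"])
        variables.append(VariableSchema(**entry))
    screens = [ScreeningRule(**dict(s)) for s in cfg.get("screens", [])]
    return variables, screens


# ---------------------------------------------------------------------------
# screening / complete cases


def apply_screens(
    table: CohortTable, rules: Iterable[ScreeningRule]
) -> tuple[CohortTable, ExclusionLog]:
    """Null every cell that offends a screening rule, logging each removal.

    Value-level removal only: rows are untouched, non-offending cells pass
    through bit-identically.
    """
    rules = list(rules)
    for r in rules:
        if r.variable not in table._by_name:
            raise SchemaError(f"screening rule references unknown variable {r.variable!r}")
    out = table.copy()
    log = ExclusionLog(n_initial=table.n, n_final=table.n)
    for rule in rules:
        col = out.data[rule.variable]
        mask = rule.offends(col)
        for row in np.flatnonzero(mask.to_numpy()):
            log.removed_values.append(
                {
                    "row": int(out.data.index[row]),
                    "variable": rule.variable,
                    "value": float(col.iloc[row]),
                    "rule": f"{rule.variable} {rule.predicate} {rule.threshold}",
                }
            )
        out.data.loc[mask, rule.variable] = np.nan
    log.validate()
    return out, log


def complete_cases(table: CohortTable) -> tuple[CohortTable, ExclusionLog]:
    """Drop every row containing at least one missing cell."""
    keep = ~table.data.isna().any(axis=1)
    dropped = table.data.index[~keep].tolist()
    if not keep.any():
        raise SchemaError("complete-case filtering removed every row")
    out = CohortTable(table.data.loc[keep].reset_index(drop=True), table.schema)
    out.check_ranges()
    log = ExclusionLog(
        removed_rows_incomplete=dropped, n_initial=table.n, n_final=out.n
    )
    log.validate()
    return out, log


def screens_from_ranges(schema: Sequence[VariableSchema]) -> list[ScreeningRule]:
    """One less_than/greater_than screen pair per range-constrained
    variable, so screening guarantees the admissible-range invariant."""
    rules: list[ScreeningRule] = []
    for v in schema:
        if v.admissible_range is not None:
            lo, hi = v.admissible_range
            rules.append(ScreeningRule(v.name, "less_than", lo))
            rules.append(ScreeningRule(v.name, "greater_than", hi))
    return rules


def default_blacklist_pairs(schema: Sequence[VariableSchema]) -> set[tuple[str, str]]:
    """Expand sink-forbidden flags into forbidden (from, to) arc pairs."""
    forbidden: set[tuple[str, str]] = set()
    names = [v.name for v in schema]
    for v in schema:
        if v.blacklist_sink_forbidden:
            forbidden.update((x, v.name) for x in names if x != v.name)
    return forbidden
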
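"""The four deterministic dataset views feeding the network ensemble.

* ``disc3`` / ``disc5`` — mutual-information-preserving discretization
  (Hartemink-style): each non-exempt variable is first cut into
  ``initial_bins`` equal-width intervals, then adjacent bins are greedily
  merged — at each step choosing the merge that loses the least total
  pairwise mutual information with all other variables — until the target
  level count remains.
* ``npn`` — nonparanormal shrinkage: dataset-wide rank-to-Gaussian
  transform, all columns rescaled by one common factor.
* ``int`` — inverse normal transformation: per-variable rank percentiles
  mapped onto a standard normal; rows attaining percentile exactly 0 or 1
  (which would map to +/- infinity) are removed and logged.

All transforms are deterministic: identical input gives byte-identical
output.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .schema import CohortTable, SchemaError

__all__ = [
    "DiscretizationSpec",
    "TransformedDataset",
    "discretize_mi",
    "npn_shrinkage",
    "int_transform",
    "make_transform_suite",
    "TRANSFORM_KINDS",
]

TRANSFORM_KINDS = ("disc3", "disc5", "npn", "int")

#: views carrying discrete codes (multinomial score family downstream)
DISCRETE_KINDS = ("disc3", "disc5")


@dataclass(frozen=True)
class DiscretizationSpec:
    """Target level count plus the initial binning used before merging."""

    levels: int
    initial_bins: int = 100
    initial_method: str = "interval"
    exempt_variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 2 <= self.levels <= self.initial_bins:
            raise ValueError(
                f"levels must satisfy 2 <= levels <= initial_bins "
                f"({self.levels} vs {self.initial_bins})"
            )
        if self.initial_method not in ("interval", "quantile"):
            raise ValueError(f"unknown initial_method {self.initial_method!r}")


def table_hash(table: CohortTable) -> str:
    """Stable content hash of a cohort table (column order included)."""
    payload = table.data.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class TransformedDataset:
    """One view of the cohort, with provenance back to its source."""

    kind: str
    table: CohortTable
    removed_rows: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def is_discrete(self) -> bool:
        return self.kind in DISCRETE_KINDS

    def matrix(self) -> np.ndarray:
        return self.table.values()

    def codes(self) -> np.ndarray:
        """Integer codes (0-based) for discrete views."""
        x = self.table.values()
        out = np.empty_like(x, dtype=np.int64)
        for j in range(x.shape[1]):
            _, out[:, j] = np.unique(x[:, j], return_inverse=True)
        return out


# ---------------------------------------------------------------------------
# discretization


def _initial_codes(col: np.ndarray, spec: DiscretizationSpec) -> tuple[np.ndarray, int]:
    """Cut one numeric column into the initial fine bins (0-based codes)."""
    lo, hi = col.min(), col.max()
    if lo == hi:
        return np.zeros(len(col), dtype=np.int64), 1
    if spec.initial_method == "interval":
        edges = np.linspace(lo, hi, spec.initial_bins + 1)
    else:
        qs = np.linspace(0, 1, spec.initial_bins + 1)
        edges = np.unique(np.quantile(col, qs))
    codes = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, len(edges) - 2)
    return codes.astype(np.int64), len(edges) - 1


def _mi_row_terms(counts: np.ndarray) -> np.ndarray:
    """Per-row contribution to the mutual information of a contingency
    table (natural-log units, unnormalized by n)."""
    n = counts.sum()
    r = counts.sum(axis=1, keepdims=True)
    s = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(counts > 0, counts * n / np.maximum(r * s, 1e-300), 1.0)
        terms = xlogy(counts, ratio)
    return terms.sum(axis=1)


def _pairwise_mi(counts: np.ndarray) -> float:
    return float(_mi_row_terms(counts).sum())


def _merge_deltas(counts: np.ndarray) -> np.ndarray:
    """MI change from merging each adjacent row pair of a contingency
    table.  Entries are <= 0 up to floating error (merging cannot gain
    information)."""
    n = counts.sum()
    s = counts.sum(axis=0, keepdims=True)
    before = _mi_row_terms(counts)
    merged = counts[:-1] + counts[1:]
    rm = merged.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(merged > 0, merged * n / np.maximum(rm * s, 1e-300), 1.0)
        after = xlogy(merged, ratio).sum(axis=1)
    return after - (before[:-1] + before[1:])


def total_pairwise_mi(code_cols: Sequence[np.ndarray], card: Sequence[int]) -> float:
    """Sum of mutual information over all unordered variable pairs."""
    p = len(code_cols)
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            tab = np.zeros((card[i], card[j]))
            np.add.at(tab, (code_cols[i], code_cols[j]), 1.0)
            total += _pairwise_mi(tab)
    return total


def _best_merge(
    v: int, code_cols: list[np.ndarray], card: list[int]
) -> tuple[int, float]:
    """Best adjacent-bin merge for variable `v` against all others:
    returns (bin index to merge with its successor, total MI delta)."""
    m = card[v]
    totals = np.zeros(m - 1)
    cv = code_cols[v]
    for u in range(len(code_cols)):
        if u == v:
            continue
        tab = np.zeros((m, card[u]))
        np.add.at(tab, (cv, code_cols[u]), 1.0)
        totals += _merge_deltas(tab)
    best = int(np.argmax(totals))  # least information lost; first index on ties
    return best, float(totals[best])


def discretize_mi(table: CohortTable, spec: DiscretizationSpec) -> TransformedDataset:
    """Discretize every non-exempt variable to ``spec.levels`` ordered
    categories by greedy pairwise-MI-preserving merging.

    Variables are visited in a round-robin sweep in schema order, each
    visit performing the single least-lossy adjacent merge for that
    variable, until all reach the target level count.  Output codes are
    1..levels in value order; exempt columns pass through unchanged.
    """
    x = table.values()
    if np.isnan(x).any():
        raise SchemaError("discretization requires a complete-case table")
    names = table.columns
    exempt = set(spec.exempt_variables)
    p = len(names)

    code_cols: list[np.ndarray] = []
    card: list[int] = []
    active: list[bool] = []
    for j, name in enumerate(names):
        if name in exempt:
            _, inv = np.unique(x[:, j], return_inverse=True)
            code_cols.append(inv.astype(np.int64))
            card.append(int(inv.max()) + 1)
            active.append(False)
        else:
            codes, m = _initial_codes(x[:, j], spec)
            if m == 1:
                warnings.warn(f"{name}: constant column yields a single category")
            code_cols.append(codes)
            card.append(m)
            active.append(True)

    # round-robin: one merge per visit until every active column is at target
    progressed = True
    while progressed:
        progressed = False
        for v in range(p):
            if active[v] and card[v] > spec.levels:
                idx, _ = _best_merge(v, code_cols, card)
                cv = code_cols[v]
                code_cols[v] = np.where(cv > idx, cv - 1, cv)
                card[v] -= 1
                progressed = True

    out = {}
    for j, name in enumerate(names):
        if name in exempt:
            out[name] = table.data[name].copy()
        else:
            # drop empty bins, relabel 1..levels in value order
            _, inv = np.unique(code_cols[j], return_inverse=True)
            out[name] = pd.Series(inv + 1.0, index=table.data.index)
    kind = f"disc{spec.levels}"
    return TransformedDataset(
        kind=kind,
        table=CohortTable(pd.DataFrame(out), table.schema),
        provenance={"kind": kind, "source_sha256": table_hash(table), "spec": spec.__dict__},
    )


# ---------------------------------------------------------------------------
# rank-to-normal transforms


def _column_ranks(x: np.ndarray) -> np.ndarray:
    """Average (mid) ranks per column, 1-based."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def npn_shrinkage(table: CohortTable) -> TransformedDataset:
    """Nonparanormal shrinkage transform.

    Each cell becomes Phi^-1(r / (n + 1)) with r its average within-column
    rank; the whole matrix is then rescaled by a single common factor (the
    sample SD of the first transformed column) toward unit column SDs.
    """
    x = table.values()
    if np.isnan(x).any():
        raise SchemaError("npn transform requires a complete-case table")
    for j, name in enumerate(table.columns):
        if np.ptp(x[:, j]) == 0:
            raise SchemaError(f"{name}: constant column cannot be rank-transformed")
    n = x.shape[0]
    z = stats.norm.ppf(_column_ranks(x) / (n + 1))
    z = z / np.std(z[:, 0], ddof=1)
    out = pd.DataFrame(z, columns=table.columns, index=table.data.index)
    return TransformedDataset(
        kind="npn",
        table=CohortTable(out, table.schema),
        provenance={"kind": "npn", "source_sha256": table_hash(table)},
    )


def int_transform(table: CohortTable) -> TransformedDataset:
    """Inverse normal transformation with extreme-percentile row removal.

    Per column: percentile = (rank - 1) / (n - 1) using average ranks.
    Any row holding a percentile of exactly 0 or 1 in any column maps to
    +/- infinity and is removed (whole observation, logged); surviving
    percentiles become Z = Phi^-1(percentile).
    """
    x = table.values()
    if np.isnan(x).any():
        raise SchemaError("int transform requires a complete-case table")
    for j, name in enumerate(table.columns):
        if np.ptp(x[:, j]) == 0:
            raise SchemaError(f"{name}: constant column cannot be rank-transformed")
    n = x.shape[0]
    pct = (_column_ranks(x) - 1.0) / (n - 1.0)
    extreme = (pct == 0.0) | (pct == 1.0)
    keep = ~extreme.any(axis=1)
    removed = table.data.index[~keep].tolist()
    if int(keep.sum()) < 3:
        raise SchemaError(
            f"int transform leaves {int(keep.sum())} rows (< 3) after removing "
            "extreme-percentile observations"
        )
    z = stats.norm.ppf(pct[keep])
    out = pd.DataFrame(z, columns=table.columns, index=table.data.index[keep])
    out = out.reset_index(drop=True)
    return TransformedDataset(
        kind="int",
        table=CohortTable(out, table.schema),
        removed_rows=removed,
        provenance={"kind": "int", "source_sha256": table_hash(table)},
    )


def make_transform_suite(
    table: CohortTable,
    spec3: DiscretizationSpec | None = None,
    spec5: DiscretizationSpec | None = None,
) -> dict[str, TransformedDataset]:
    """Build the four views {disc3, disc5, npn, int}, each independently
    derived from the same post-exclusion complete-case table."""
    exempt = tuple(v.name for v in table.schema if v.discretization_exempt)
    if spec3 is None:
        spec3 = DiscretizationSpec(levels=3, exempt_variables=exempt)
    if spec5 is None:
        spec5 = DiscretizationSpec(levels=5, exempt_variables=exempt)
    if spec3.levels != 3 or spec5.levels != 5:
        raise ValueError("spec3/spec5 must target 3 and 5 levels respectively")
    return {
        "disc3": discretize_mi(table, spec3),
        "disc5": discretize_mi(table, spec5),
        "npn": npn_shrinkage(table),
        "int": int_transform(table),
    }
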
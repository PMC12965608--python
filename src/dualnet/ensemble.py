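"""Bootstrap consensus ensemble over the (algorithm x transformation) grid.

Each of the 16 grid cells pairs one structure learner (hc / tabu / mmhc /
h2pc) with one dataset view (disc3 / disc5 / npn / int).  Per cell, B
bootstrap resamples are learned and averaged into per-pair strength
(containment fraction) and direction (orientation fraction) statistics.
Ad-hoc thresholding turns each cell into a fully directed subnetwork:
pairs kept only with strength >= 85% and a strict orientation majority
(> B/2 resamples).  The cross-grid consensus keeps an arc only when it is
retained under *all* algorithms within at least three of the four
transformations — a minimum presence of 12 of the 16 subnetworks — and
attaches learned/grand strength and direction statistics (grand = learned
x k/16, absent cells contributing zero).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .rpcn import RPCNetwork
from .structure import ALGORITHMS, Blacklist, CITestSpec, learn_structure
from .transforms import TRANSFORM_KINDS, TransformedDataset

__all__ = [
    "EnsembleConfig",
    "ArcStrengthTable",
    "SubnetworkDAG",
    "ConsensusArc",
    "ConsensusGraph",
    "OverlapReport",
    "bootstrap_arc_strength",
    "adhoc_threshold",
    "run_ensemble",
    "consensus_graph",
    "arc_statistics",
    "dual_network_overlap",
    "min_retention_count",
    "min_direction_count",
    "min_consensus_cells",
    "implied_presence_instances",
    "cell_seed",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Grid, bootstrap, and thresholding configuration.

    ``direction_min_count`` defaults to the strict majority floor(B/2)+1
    (5,001 when B = 10,000).
    """

    B: int = 10_000
    strength_min: float = 0.85
    direction_min_count: int | None = None
    algorithms: tuple[str, ...] = ALGORITHMS
    transformations: tuple[str, ...] = TRANSFORM_KINDS
    min_transformations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.strength_min <= 1:
            raise ValueError("strength_min must lie in (0, 1]")
        if self.B < 1:
            raise ValueError("B must be positive")
        if self.direction_min_count is not None and self.direction_min_count <= self.B / 2:
            raise ValueError("direction_min_count must exceed B/2")
        if not 1 <= self.min_transformations <= len(self.transformations):
            raise ValueError("min_transformations out of range")

    @property
    def direction_count(self) -> int:
        if self.direction_min_count is not None:
            return self.direction_min_count
        return self.B // 2 + 1

    @property
    def K(self) -> int:
        return len(self.algorithms) * len(self.transformations)

    # shared rule predicates — every threshold query goes through these
    def retains(self, present_count: float) -> bool:
        return present_count / self.B >= self.strength_min

    def orients(self, oriented_count: float) -> bool:
        return oriented_count >= self.direction_count


def cell_seed(master_seed: int, algorithm: str, transformation: str) -> np.random.SeedSequence:
    """Per-cell seed derived from stable label hashes, so cells are
    independent of grid ordering and of each other."""
    def h(label: str) -> int:
        return int.from_bytes(hashlib.sha256(label.encode()).digest()[:8], "big")

    return np.random.SeedSequence([master_seed, h(algorithm), h(transformation)])


# ---------------------------------------------------------------------------
# per-cell bootstrap


class _ResampledView:
    """Lightweight row-resampled stand-in for a TransformedDataset."""

    def __init__(self, parent: TransformedDataset, rows: np.ndarray):
        self.kind = parent.kind
        self.is_discrete = parent.is_discrete
        self._x = parent.matrix()[rows]
        self.table = _TableShim(parent.table.columns, parent.table._by_name, self._x)

    def matrix(self) -> np.ndarray:
        return self._x

    def codes(self) -> np.ndarray:
        out = np.empty_like(self._x, dtype=np.int64)
        for j in range(self._x.shape[1]):
            _, out[:, j] = np.unique(self._x[:, j], return_inverse=True)
        return out


class _TableShim:
    def __init__(self, columns, by_name, x):
        self.columns = list(columns)
        self._by_name = by_name
        self._x = x

    def variable(self, name):
        return self._by_name[name]


@dataclass
class ArcStrengthTable:
    """Bootstrap-averaged containment and orientation counts for one cell.

    ``present[pair]`` counts resampled structures containing the unordered
    pair; ``oriented[(u, v)]`` counts those orienting it u -> v, with
    undirected occurrences (defensive path) contributing 1/2 to each.
    """

    algorithm: str
    transformation: str
    B: int
    nodes: list[str]
    present: dict = field(default_factory=dict)
    oriented: dict = field(default_factory=dict)
    n_failures: int = 0

    def strength(self, pair: frozenset) -> float:
        return self.present.get(pair, 0) / self.B

    def direction(self, u: str, v: str) -> float:
        """Fraction of edge-containing resamples orienting u -> v."""
        present = self.present.get(frozenset((u, v)), 0)
        if present == 0:
            return 0.0
        return self.oriented.get((u, v), 0.0) / present

    def validate(self) -> None:
        for pair, cnt in self.present.items():
            u, v = sorted(pair)
            total = self.oriented.get((u, v), 0.0) + self.oriented.get((v, u), 0.0)
            if abs(total - cnt) > 1e-9:
                raise AssertionError(f"orientation counts do not sum for {u}--{v}")


def bootstrap_arc_strength(
    view: TransformedDataset,
    algorithm: str,
    config: EnsembleConfig,
    blacklist: Blacklist = Blacklist(),
    test: CITestSpec = CITestSpec(),
    seed: np.random.SeedSequence | int | None = None,
) -> ArcStrengthTable:
    """Learn B bootstrap structures and tabulate arc strength/direction.

    A learner failure on a resample triggers one redraw; a second failure
    counts the resample as structure-absent with a warning.
    """
    if seed is None:
        seed = cell_seed(config.seed, algorithm, view.kind)
    rng = np.random.default_rng(seed)
    n = view.matrix().shape[0]
    table = ArcStrengthTable(
        algorithm=algorithm, transformation=view.kind, B=config.B,
        nodes=view.table.columns,
    )
    for _ in range(config.B):
        dag = None
        for attempt in range(2):
            rows = rng.integers(0, n, n)
            try:
                dag = learn_structure(_ResampledView(view, rows), algorithm,
                                      blacklist=blacklist, test=test)
                break
            except Exception as exc:  # noqa: BLE001 - resample-level guard
                if attempt == 1:
                    warnings.warn(
                        f"[{algorithm}/{view.kind}] resample failed twice "
                        f"({exc}); counted as structure-absent"
                    )
                    table.n_failures += 1
        if dag is None:
            continue
        for u, v in dag.arcs:
            pair = frozenset((u, v))
            table.present[pair] = table.present.get(pair, 0) + 1
            table.oriented[(u, v)] = table.oriented.get((u, v), 0.0) + 1.0
    table.validate()
    return table


# ---------------------------------------------------------------------------
# thresholding


@dataclass
class SubnetworkDAG:
    """One cell's thresholded, fully directed subnetwork."""

    algorithm: str
    transformation: str
    B: int
    nodes: list[str]
    arcs: dict = field(default_factory=dict)  # (u, v) -> {"s": float, "d": float}
    dropped_direction_unresolved: list = field(default_factory=list)

    @property
    def cell(self) -> tuple[str, str]:
        return (self.algorithm, self.transformation)

    def pairs(self) -> set[frozenset]:
        return {frozenset(a) for a in self.arcs}

    def contains_pair(self, pair: frozenset) -> bool:
        return pair in self.pairs()

    def direction_of(self, u: str, v: str) -> float:
        """Oriented fraction of u -> v among edge-containing resamples,
        derivable from either stored orientation."""
        if (u, v) in self.arcs:
            return self.arcs[(u, v)]["d"]
        if (v, u) in self.arcs:
            return 1.0 - self.arcs[(v, u)]["d"]
        raise KeyError(f"{u}--{v} not retained in cell {self.cell}")

    def strength_of(self, pair: frozenset) -> float:
        u, v = sorted(pair)
        if (u, v) in self.arcs:
            return self.arcs[(u, v)]["s"]
        return self.arcs[(v, u)]["s"]


def adhoc_threshold(table: ArcStrengthTable, config: EnsembleConfig) -> SubnetworkDAG:
    """Retain pairs with strength >= strength_min, orienting toward the
    direction holding a strict bootstrap majority; strength-qualified
    pairs without a direction majority are dropped and logged.  The result
    is audited for acyclicity (cycle -> error)."""
    sub = SubnetworkDAG(
        algorithm=table.algorithm, transformation=table.transformation,
        B=table.B, nodes=list(table.nodes),
    )
    for pair, cnt in sorted(table.present.items(), key=lambda kv: sorted(kv[0])):
        if not config.retains(cnt):
            continue
        u, v = sorted(pair)
        c_uv = table.oriented.get((u, v), 0.0)
        c_vu = table.oriented.get((v, u), 0.0)
        if config.orients(c_uv):
            sub.arcs[(u, v)] = {"s": cnt / table.B, "d": c_uv / cnt}
        elif config.orients(c_vu):
            sub.arcs[(v, u)] = {"s": cnt / table.B, "d": c_vu / cnt}
        else:
            sub.dropped_direction_unresolved.append((u, v, c_uv, c_vu))
    cycle = _find_cycle(sub.nodes, set(sub.arcs))
    if cycle is not None:
        raise RuntimeError(
            f"cell {sub.cell}: thresholded subnetwork contains a cycle {cycle}"
        )
    return sub


def _find_cycle(nodes: Sequence[str], arcs: set[tuple[str, str]]) -> list[str] | None:
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in arcs:
        children[u].append(v)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {v: WHITE for v in nodes}
    stack_path: list[str] = []

    def dfs(u: str) -> list[str] | None:
        color[u] = GREY
        stack_path.append(u)
        for w in children[u]:
            if color[w] == GREY:
                return stack_path[stack_path.index(w):] + [w]
            if color[w] == WHITE:
                found = dfs(w)
                if found:
                    return found
        color[u] = BLACK
        stack_path.pop()
        return None

    for v in nodes:
        if color[v] == WHITE:
            found = dfs(v)
            if found:
                return found
    return None


# ---------------------------------------------------------------------------
# ensemble and consensus


def run_ensemble(
    suite: Mapping[str, TransformedDataset],
    config: EnsembleConfig,
    blacklist: Blacklist = Blacklist(),
    test: CITestSpec = CITestSpec(),
    progress: bool = False,
) -> dict[tuple[str, str], SubnetworkDAG]:
    """One thresholded subnetwork per (algorithm, transformation) cell.

    Cell seeds derive from the master seed and the cell labels only, so
    results are independent of grid ordering.
    """
    missing = [k for k in config.transformations if k not in suite]
    if missing:
        raise ValueError(f"transform suite is missing views: {missing}")
    out: dict[tuple[str, str], SubnetworkDAG] = {}
    for algo in config.algorithms:
        for kind in config.transformations:
            if progress:
                print(f"[ensemble] cell {algo} x {kind} (B={config.B})", flush=True)
            try:
                table = bootstrap_arc_strength(
                    suite[kind], algo, config, blacklist, test,
                    seed=cell_seed(config.seed, algo, kind),
                )
                out[(algo, kind)] = adhoc_threshold(table, config)
            except Exception as exc:
                raise RuntimeError(f"ensemble cell ({algo}, {kind}) failed: {exc}") from exc
    return out


@dataclass
class ConsensusArc:
    from_: str
    to: str
    k: int
    learned_strength: float
    grand_strength: float
    learned_direction: float
    grand_direction: float
    cells: tuple = ()

    def validate(self, K: int) -> None:
        assert self.k <= K
        assert abs(self.grand_strength - self.learned_strength * self.k / K) <= 1e-12
        assert abs(self.grand_direction - self.learned_direction * self.k / K) <= 1e-12


@dataclass
class ConsensusGraph:
    nodes: list[str]
    arcs: list[ConsensusArc]
    K: int
    acyclic: bool
    cycle: list | None = None

    def arc_pairs(self) -> set[frozenset]:
        return {frozenset((a.from_, a.to)) for a in self.arcs}

    def low_grand_direction(self, threshold: float = 0.5) -> list[ConsensusArc]:
        return [a for a in self.arcs if a.grand_direction < threshold]

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "K": self.K,
            "acyclic": self.acyclic,
            "cycle": self.cycle,
            "arcs": [
                {
                    "from": a.from_, "to": a.to, "networks": a.k,
                    "learned_strength": a.learned_strength,
                    "grand_strength": a.grand_strength,
                    "learned_direction": a.learned_direction,
                    "grand_direction": a.grand_direction,
                    "cells": [list(c) for c in a.cells],
                }
                for a in self.arcs
            ],
        }


def pattern_qualifies(
    present_cells: set[tuple[str, str]],
    algorithms: Sequence[str],
    transformations: Sequence[str],
    min_transformations: int,
) -> bool:
    """The consensus predicate on a cell-presence pattern: at least
    `min_transformations` transformations in which the pair is present
    under every algorithm."""
    full_transforms = sum(
        1 for t in transformations
        if all((a, t) in present_cells for a in algorithms)
    )
    return full_transforms >= min_transformations


def arc_statistics(
    subnets: Mapping[tuple[str, str], SubnetworkDAG],
    pair: frozenset,
    config: EnsembleConfig,
) -> ConsensusArc:
    """Learned/grand strength and direction for one unordered pair.

    k counts containing subnetworks orientation-agnostically; learned
    statistics average over those k cells, grand statistics average over
    all K cells with absent cells contributing zero (and are cross-checked
    against learned x k/K)."""
    containing = [
        (cell, sub) for cell, sub in subnets.items() if pair in sub.pairs()
    ]
    if not containing:
        raise ValueError(f"pair {sorted(pair)} retained in no subnetwork")
    K = config.K
    k = len(containing)
    u, v = sorted(pair)
    strengths = [sub.strength_of(pair) for _, sub in containing]
    d_uv = [sub.direction_of(u, v) for _, sub in containing]
    learned_strength = float(np.mean(strengths))
    mean_d_uv = float(np.mean(d_uv))
    if mean_d_uv >= 0.5:
        frm, to, learned_direction = u, v, mean_d_uv
    else:
        frm, to, learned_direction = v, u, 1.0 - mean_d_uv
    # independent grand computation: mean over all K cells, zeros when absent
    grand_strength = float(sum(strengths)) / K
    grand_direction = (
        float(sum(sub.direction_of(frm, to) for _, sub in containing)) / K
    )
    arc = ConsensusArc(
        from_=frm, to=to, k=k,
        learned_strength=learned_strength, grand_strength=grand_strength,
        learned_direction=learned_direction, grand_direction=grand_direction,
        cells=tuple(sorted(cell for cell, _ in containing)),
    )
    arc.validate(K)
    return arc


def consensus_graph(
    subnets: Mapping[tuple[str, str], SubnetworkDAG],
    config: EnsembleConfig,
) -> ConsensusGraph:
    """Cross-grid consensus: an arc qualifies when retained under all
    algorithms within at least `min_transformations` transformations.
    The final graph's acyclicity is audited and reported (not repaired)."""
    expected = {(a, t) for a in config.algorithms for t in config.transformations}
    if set(subnets) != expected:
        raise ValueError("subnetwork grid does not cover the configured cells")
    nodes = next(iter(subnets.values())).nodes
    all_pairs: set[frozenset] = set()
    for sub in subnets.values():
        all_pairs |= sub.pairs()
    arcs = []
    for pair in sorted(all_pairs, key=sorted):
        present_cells = {cell for cell, sub in subnets.items() if pair in sub.pairs()}
        if pattern_qualifies(
            present_cells, config.algorithms, config.transformations,
            config.min_transformations,
        ):
            arcs.append(arc_statistics(subnets, pair, config))
    arcs.sort(key=lambda a: (a.from_, a.to))
    cycle = _find_cycle(nodes, {(a.from_, a.to) for a in arcs})
    return ConsensusGraph(
        nodes=list(nodes), arcs=arcs, K=config.K,
        acyclic=cycle is None, cycle=cycle,
    )


# ---------------------------------------------------------------------------
# bookkeeping derived from the implemented rules


def min_retention_count(config: EnsembleConfig) -> int:
    """Smallest bootstrap count satisfying the retention rule."""
    for c in range(config.B + 1):
        if config.retains(c):
            return c
    raise RuntimeError("retention rule satisfiable by no count")


def min_direction_count(config: EnsembleConfig) -> int:
    """Smallest oriented count accepted by the strict direction majority."""
    for c in range(config.B + 1):
        if config.orients(c):
            return c
    raise RuntimeError("direction rule satisfiable by no count")


def min_consensus_cells(config: EnsembleConfig) -> int:
    """Minimum cell count among qualifying presence patterns, by
    exhaustive enumeration of the 2^K patterns through the implemented
    consensus predicate."""
    cells = [(a, t) for a in config.algorithms for t in config.transformations]
    K = len(cells)
    best = None
    for mask in range(1 << K):
        present = {cells[i] for i in range(K) if mask >> i & 1}
        if pattern_qualifies(
            present, config.algorithms, config.transformations,
            config.min_transformations,
        ):
            cnt = len(present)
            if best is None or cnt < best:
                best = cnt
    if best is None:
        raise RuntimeError("no presence pattern satisfies the consensus rule")
    return best


def implied_presence_instances(avg_grand_strength: float, config: EnsembleConfig) -> int:
    """Expected bootstrapped presence count over all K x B slots implied
    by an average grand strength."""
    return round(avg_grand_strength * config.K * config.B)


# ---------------------------------------------------------------------------
# dual-network overlap


@dataclass
class OverlapReport:
    n_rpcn_edges: int
    n_shared: int
    shared_percentage: float
    welch_t: float | None = None
    welch_df: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    mean_shared: float | None = None
    mean_unique: float | None = None

    @property
    def comparison_applicable(self) -> bool:
        return self.welch_t is not None


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float, float]:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    crit = sps.t.ppf(0.975, df)
    diff = a.mean() - b.mean()
    return t, df, diff - crit * math.sqrt(se2), diff + crit * math.sqrt(se2), p


def dual_network_overlap(rpcn: RPCNetwork, consensus: ConsensusGraph) -> OverlapReport:
    """Shared-edge count/percentage between the undirected network and the
    consensus DAG, plus a Welch two-sample t comparison of absolute RPCN
    edge weights for shared vs non-shared edges."""
    if set(rpcn.nodes) != set(consensus.nodes):
        raise ValueError("networks are defined over different node sets")
    rpcn_pairs = rpcn.edge_pairs()
    dag_pairs = consensus.arc_pairs()
    shared = rpcn_pairs & dag_pairs
    n_edges = len(rpcn_pairs)
    pct = 100.0 * len(shared) / n_edges if n_edges else 0.0
    idx = {n: i for i, n in enumerate(rpcn.nodes)}
    shared_w, unique_w = [], []
    for pair in rpcn_pairs:
        i, j = (idx[x] for x in sorted(pair))
        w = abs(rpcn.weights[i, j])
        (shared_w if pair in shared else unique_w).append(w)
    report = OverlapReport(
        n_rpcn_edges=n_edges, n_shared=len(shared),
        shared_percentage=pct,
    )
    if len(shared_w) >= 2 and len(unique_w) >= 2:
        t, df, lo, hi, p = _welch(np.asarray(shared_w), np.asarray(unique_w))
        report.welch_t, report.welch_df = float(t), float(df)
        report.ci_low, report.ci_high, report.p_value = float(lo), float(hi), float(p)
        report.mean_shared = float(np.mean(shared_w))
        report.mean_unique = float(np.mean(unique_w))
    return report
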
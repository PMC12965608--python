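"""Bayesian network structure learning.

Four learners over a declared blacklist:

* ``hill_climb`` — greedy add/delete/reverse search from the empty graph
  under a decomposable score (BIC, discrete multinomial or Gaussian).
* ``tabu_search`` — hill climbing with a fixed-length list of recently
  visited structures and a bounded number of non-improving moves.
* ``hybrid_learn`` (``mmhc`` / ``h2pc``) — restrict-then-maximize: a
  constraint-based skeleton (max-min or hybrid parents-and-children, CI
  tests at alpha) confines arc additions; deletions and reversals stay
  unrestricted.

All searches are deterministic given the data: no random restarts, and
equal-score moves break ties lexicographically by (from, to).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from scipy.special import chdtrc, erfc, xlogy

from .transforms import TransformedDataset

__all__ = [
    "DAGStructure",
    "Blacklist",
    "CITestSpec",
    "DiscreteBICScore",
    "GaussianBICScore",
    "make_score",
    "score_dag",
    "hill_climb",
    "tabu_search",
    "learn_skeleton",
    "hybrid_learn",
    "learn_structure",
    "ALGORITHMS",
]

ALGORITHMS = ("hc", "tabu", "mmhc", "h2pc")


# ---------------------------------------------------------------------------
# DAG


@dataclass
class DAGStructure:
    """Node list plus a set of directed arcs; always acyclic."""

    nodes: list[str]
    arcs: set[tuple[str, str]] = field(default_factory=set)
    truncated: bool = False

    def __post_init__(self) -> None:
        for u, v in self.arcs:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
        if self.topological_order() is None:
            raise ValueError("arc set contains a cycle")

    def parents(self, v: str) -> set[str]:
        return {u for (u, w) in self.arcs if w == v}

    def indegree(self, v: str) -> int:
        return sum(1 for (_, w) in self.arcs if w == v)

    def skeleton(self) -> set[frozenset]:
        return {frozenset(a) for a in self.arcs}

    def topological_order(self) -> list[str] | None:
        indeg = {v: 0 for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.arcs:
            indeg[v] += 1
            children[u].append(v)
        queue = sorted(v for v in self.nodes if indeg[v] == 0)
        order = []
        while queue:
            u = queue.pop(0)
            order.append(u)
            for w in sorted(children[u]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
            queue.sort()
        return order if len(order) == len(self.nodes) else None

    def is_acyclic(self) -> bool:
        return self.topological_order() is not None

    def cpdag_key(self) -> tuple:
        """Canonical key of the Markov equivalence class (skeleton +
        v-structures)."""
        skel = frozenset(self.skeleton())
        vstruct = set()
        for v in self.nodes:
            ps = sorted(self.parents(v))
            for a, b in itertools.combinations(ps, 2):
                if frozenset((a, b)) not in skel:
                    vstruct.add((a, b, v))
        return (skel, frozenset(vstruct))

    def copy(self) -> "DAGStructure":
        return DAGStructure(list(self.nodes), set(self.arcs), self.truncated)

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "arcs": sorted(self.arcs)}

    @classmethod
    def from_dict(cls, d: dict) -> "DAGStructure":
        return cls(list(d["nodes"]), {tuple(a) for a in d["arcs"]})


@dataclass(frozen=True)
class Blacklist:
    """Forbidden arcs: explicit ordered pairs plus sink-forbidden
    variables, which expand to every arc pointing into them."""

    forbidden: frozenset = frozenset()
    sink_forbidden: frozenset = frozenset()

    @classmethod
    def from_sinks(cls, names: Iterable[str]) -> "Blacklist":
        return cls(sink_forbidden=frozenset(names))

    @classmethod
    def empty(cls) -> "Blacklist":
        return cls()

    def forbids(self, u: str, v: str) -> bool:
        return (u, v) in self.forbidden or v in self.sink_forbidden

    def expand(self, nodes: Sequence[str]) -> set[tuple[str, str]]:
        out = set(self.forbidden)
        for v in self.sink_forbidden:
            out.update((x, v) for x in nodes if x != v)
        return out

    def audit(self, dag: DAGStructure) -> None:
        bad = [a for a in dag.arcs if self.forbids(*a)]
        if bad:
            raise AssertionError(f"blacklist violated by arcs: {sorted(bad)}")


# ---------------------------------------------------------------------------
# scores


class _ScoreBase:
    """Decomposable score with a (node, parent-set) cache."""

    nodes: list[str]

    def __init__(self) -> None:
        self._cache: dict[tuple[int, frozenset], float] = {}

    def _local(self, v: int, parents: frozenset) -> float:
        raise NotImplementedError

    def local_score(self, v: int, parents: Iterable[int]) -> float:
        key = (v, frozenset(parents))
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = self._local(v, key[1])
        return hit

    def index(self, name: str) -> int:
        return self.nodes.index(name)

    def total(self, dag: DAGStructure) -> float:
        idx = {n: i for i, n in enumerate(self.nodes)}
        return sum(
            self.local_score(idx[v], frozenset(idx[u] for u in dag.parents(v)))
            for v in dag.nodes
        )


class DiscreteBICScore(_ScoreBase):
    """BIC for multinomial CPTs: loglik - (log n / 2) * (r_v - 1) * q,
    with q the number of parent configurations.  Zero-count cells follow
    the MLE convention 0*log 0 = 0."""

    family = "bic_discrete"

    def __init__(self, codes: np.ndarray, nodes: Sequence[str]):
        super().__init__()
        self.codes = np.asarray(codes, dtype=np.int64)
        self.n, self.p = self.codes.shape
        self.card = (self.codes.max(axis=0) + 1).astype(np.int64)
        self.nodes = list(nodes)
        self._logn2 = np.log(self.n) / 2.0

    def _local(self, v: int, parents: frozenset) -> float:
        r = int(self.card[v])
        ps = sorted(parents)
        if not ps:
            counts = np.bincount(self.codes[:, v], minlength=r).astype(float)
            ll = float(xlogy(counts, counts / self.n).sum())
            return ll - self._logn2 * (r - 1)
        q = 1
        cfg = np.zeros(self.n, dtype=np.int64)
        for u in ps:
            cfg = cfg * self.card[u] + self.codes[:, u]
            q *= int(self.card[u])
        joint = np.bincount(cfg * r + self.codes[:, v], minlength=q * r).astype(float)
        joint = joint.reshape(q, r)
        marg = joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(xlogy(joint, np.where(joint > 0, joint / np.maximum(marg, 1), 1)).sum())
        return ll - self._logn2 * (r - 1) * q


class GaussianBICScore(_ScoreBase):
    """BIC for linear-Gaussian CPDs: loglik - (log n / 2) * (k + 2)
    parameters per node (k coefficients, intercept, residual variance)."""

    family = "bic_gaussian"

    def __init__(self, x: np.ndarray, nodes: Sequence[str]):
        super().__init__()
        x = np.asarray(x, dtype=float)
        self.n, self.p = x.shape
        xc = x - x.mean(axis=0)
        self.S = xc.T @ xc / self.n  # MLE covariance
        self.nodes = list(nodes)
        self._logn2 = np.log(self.n) / 2.0

    def _local(self, v: int, parents: frozenset) -> float:
        ps = sorted(parents)
        if ps:
            Spp = self.S[np.ix_(ps, ps)]
            Spv = self.S[ps, v]
            try:
                beta = np.linalg.solve(Spp, Spv)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Spp, Spv, rcond=None)[0]
            sigma2 = float(self.S[v, v] - Spv @ beta)
        else:
            sigma2 = float(self.S[v, v])
        sigma2 = max(sigma2, 1e-12)
        ll = -0.5 * self.n * (np.log(2 * np.pi * sigma2) + 1.0)
        return ll - self._logn2 * (len(ps) + 2)


def make_score(dataset: TransformedDataset) -> _ScoreBase:
    """Score family matched to the view: discrete BIC for discretized
    views, Gaussian BIC otherwise."""
    nodes = dataset.table.columns
    if dataset.is_discrete:
        return DiscreteBICScore(dataset.codes(), nodes)
    return GaussianBICScore(dataset.matrix(), nodes)


def score_dag(dag: DAGStructure, dataset_or_score, spec: str | None = None):
    """Total decomposable score of a DAG plus its per-node decomposition."""
    score = dataset_or_score if isinstance(dataset_or_score, _ScoreBase) else make_score(dataset_or_score)
    if spec is not None and spec != score.family:
        raise ValueError(f"score family mismatch: requested {spec}, data gives {score.family}")
    idx = {n: i for i, n in enumerate(score.nodes)}
    per_node = {
        v: score.local_score(idx[v], frozenset(idx[u] for u in dag.parents(v)))
        for v in dag.nodes
    }
    return sum(per_node.values()), per_node


# ---------------------------------------------------------------------------
# greedy search


def _reachable(children: dict[int, set[int]], src: int, dst: int) -> bool:
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


class _SearchState:
    def __init__(self, score: _ScoreBase, blacklist: Blacklist,
                 allowed_pairs: set[frozenset] | None):
        self.score = score
        self.nodes = score.nodes
        self.p = len(self.nodes)
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        self.parents: list[set[int]] = [set() for _ in range(self.p)]
        self.children: dict[int, set[int]] = {i: set() for i in range(self.p)}
        bl = blacklist.expand(self.nodes)
        self.forbidden = {(self.idx[u], self.idx[v]) for u, v in bl}
        if allowed_pairs is None:
            self.allowed = None
        else:
            self.allowed = set()
            for pair in allowed_pairs:
                a, b = tuple(pair)
                self.allowed.add(frozenset((self.idx[a], self.idx[b])))
        self.total = sum(score.local_score(v, frozenset()) for v in range(self.p))

    def local(self, v: int) -> float:
        return self.score.local_score(v, frozenset(self.parents[v]))

    def arc_set(self) -> frozenset:
        return frozenset(
            (u, v) for v in range(self.p) for u in self.parents[v]
        )

    # -- move enumeration ----------------------------------------------
    def moves(self):
        """Yield (delta, kind, u, v) for every legal move, in
        deterministic lexicographic order."""
        sc = self.score.local_score
        for u in range(self.p):
            for v in range(self.p):
                if u == v:
                    continue
                if u in self.parents[v]:
                    # deletion
                    base = self.local(v)
                    delta = sc(v, frozenset(self.parents[v] - {u})) - base
                    yield (delta, "del", u, v)
                    # reversal u->v to v->u
                    if (v, u) not in self.forbidden and v not in self.parents[u]:
                        self.parents[v].discard(u)
                        self.children[u].discard(v)
                        cyc = _reachable(self.children, u, v)
                        self.parents[v].add(u)
                        self.children[u].add(v)
                        if not cyc:
                            d1 = sc(v, frozenset(self.parents[v] - {u})) - base
                            d2 = sc(u, frozenset(self.parents[u] | {v})) - self.local(u)
                            yield (d1 + d2, "rev", u, v)
                else:
                    # addition
                    if (u, v) in self.forbidden:
                        continue
                    if self.allowed is not None and frozenset((u, v)) not in self.allowed:
                        continue
                    if _reachable(self.children, v, u):
                        continue
                    delta = sc(v, frozenset(self.parents[v] | {u})) - self.local(v)
                    yield (delta, "add", u, v)

    def apply(self, kind: str, u: int, v: int) -> None:
        if kind == "add":
            d = (self.score.local_score(v, frozenset(self.parents[v] | {u}))
                 - self.local(v))
            self.parents[v].add(u)
            self.children[u].add(v)
        elif kind == "del":
            d = (self.score.local_score(v, frozenset(self.parents[v] - {u}))
                 - self.local(v))
            self.parents[v].discard(u)
            self.children[u].discard(v)
        else:  # rev
            d1 = (self.score.local_score(v, frozenset(self.parents[v] - {u}))
                  - self.local(v))
            d2 = (self.score.local_score(u, frozenset(self.parents[u] | {v}))
                  - self.local(u))
            d = d1 + d2
            self.parents[v].discard(u)
            self.children[u].discard(v)
            self.parents[u].add(v)
            self.children[v].add(u)
        self.total += d

    def to_dag(self, truncated: bool = False) -> DAGStructure:
        arcs = {
            (self.nodes[u], self.nodes[v])
            for v in range(self.p)
            for u in self.parents[v]
        }
        return DAGStructure(list(self.nodes), arcs, truncated=truncated)


_EPS = 1e-9


def _best_move(state: _SearchState, tabu: set[frozenset] | None = None):
    """Highest-delta legal move; lexicographic (from, to, kind) tie-break
    via first-encountered-wins over the deterministic enumeration."""
    best = None
    for delta, kind, u, v in state.moves():
        if tabu is not None:
            nxt = _next_arcs(state, kind, u, v)
            if nxt in tabu:
                continue
        if best is None or delta > best[0] + _EPS:
            best = (delta, kind, u, v)
    return best


def _next_arcs(state: _SearchState, kind: str, u: int, v: int) -> frozenset:
    arcs = set(state.arc_set())
    if kind == "add":
        arcs.add((u, v))
    elif kind == "del":
        arcs.discard((u, v))
    else:
        arcs.discard((u, v))
        arcs.add((v, u))
    return frozenset(arcs)


def hill_climb(
    data: TransformedDataset | _ScoreBase,
    blacklist: Blacklist = Blacklist(),
    max_iter: int = 10_000,
    allowed_pairs: set[frozenset] | None = None,
    seed: int | None = None,
) -> DAGStructure:
    """Greedy hill climbing from the empty graph.

    Each step takes the single strictly score-improving add/delete/reverse
    move with the largest gain (acyclicity and blacklist respected);
    terminates at a local optimum.  Deterministic given the data — `seed`
    is accepted for interface uniformity only.
    """
    score = data if isinstance(data, _ScoreBase) else make_score(data)
    if len(score.nodes) < 2:
        raise ValueError("need at least 2 variables")
    state = _SearchState(score, blacklist, allowed_pairs)
    for _ in range(max_iter):
        move = _best_move(state)
        if move is None or move[0] <= _EPS:
            dag = state.to_dag()
            blacklist.audit(dag)
            return dag
        state.apply(*move[1:])
    dag = state.to_dag(truncated=True)
    blacklist.audit(dag)
    return dag


def tabu_search(
    data: TransformedDataset | _ScoreBase,
    blacklist: Blacklist = Blacklist(),
    tabu_length: int = 10,
    max_worsening_moves: int = 10,
    max_iter: int = 10_000,
    allowed_pairs: set[frozenset] | None = None,
    seed: int | None = None,
) -> DAGStructure:
    """Hill climbing with a fixed-length tabu list of recently visited
    structures and a bounded number of non-improving moves; returns the
    best structure visited (never worse than plain hill climbing)."""
    score = data if isinstance(data, _ScoreBase) else make_score(data)
    if len(score.nodes) < 2:
        raise ValueError("need at least 2 variables")
    state = _SearchState(score, blacklist, allowed_pairs)
    visited: list[frozenset] = [state.arc_set()]
    best_arcs, best_total = state.arc_set(), state.total
    worsening = 0
    truncated = False
    for it in range(max_iter):
        tabu = set(visited[-tabu_length:]) if tabu_length > 0 else None
        move = _best_move(state, tabu)
        if move is None:
            break
        delta = move[0]
        if delta <= _EPS:
            if worsening >= max_worsening_moves:
                break
            worsening += 1
        state.apply(*move[1:])
        visited.append(state.arc_set())
        if state.total > best_total + _EPS:
            best_total = state.total
            best_arcs = state.arc_set()
            worsening = 0
    else:
        truncated = True
    nodes = score.nodes
    dag = DAGStructure(
        list(nodes),
        {(nodes[u], nodes[v]) for u, v in best_arcs},
        truncated=truncated,
    )
    blacklist.audit(dag)
    return dag


# ---------------------------------------------------------------------------
# conditional-independence tests and skeletons


@dataclass(frozen=True)
class CITestSpec:
    """CI test configuration: mutual-information G-test for discrete data,
    Fisher-z on partial correlations for continuous data."""

    alpha: float = 0.05
    max_condition: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


class CITester:
    """P-values for X independent of Y given Z on one dataset view."""

    def __init__(self, dataset: TransformedDataset, spec: CITestSpec = CITestSpec()):
        self.spec = spec
        self._cache: dict[tuple, float] = {}
        self.nodes = dataset.table.columns
        self.p = len(self.nodes)
        self.discrete = dataset.is_discrete
        if self.discrete:
            self.codes = dataset.codes()
            self.card = self.codes.max(axis=0) + 1
            self.n = self.codes.shape[0]
        else:
            x = dataset.matrix()
            self.n = x.shape[0]
            sd = x.std(axis=0)
            if np.any(sd == 0):
                warnings.warn("constant column; CI tests involving it are skipped")
            sd = np.where(sd == 0, 1.0, sd)
            self.corr = np.corrcoef(x, rowvar=False)
            self.corr = np.nan_to_num(self.corr, nan=0.0)

    def reliable(self, x: int, y: int, z: tuple[int, ...] = ()) -> bool:
        """Heuristic test-reliability guard: a discrete test needs at
        least 5 observations per degree of freedom, else it has no power
        and is skipped rather than read as independence."""
        if not self.discrete:
            return self.n - len(z) - 3 > 0
        df = (self.card[x] - 1) * (self.card[y] - 1)
        for u in z:
            df *= self.card[u]
        return self.n >= 5 * df

    def pvalue(self, x: int, y: int, z: tuple[int, ...] = ()) -> float:
        if x > y:
            x, y = y, x
        key = (x, y, z)
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = (
                self._discrete_g2(x, y, z) if self.discrete else self._fisher_z(x, y, z)
            )
        return hit

    def _discrete_g2(self, x: int, y: int, z: tuple[int, ...]) -> float:
        rx, ry = int(self.card[x]), int(self.card[y])
        q = 1
        cfg = np.zeros(self.n, dtype=np.int64)
        for u in z:
            cfg = cfg * self.card[u] + self.codes[:, u]
            q *= int(self.card[u])
        joint = np.bincount(
            (cfg * rx + self.codes[:, x]) * ry + self.codes[:, y],
            minlength=q * rx * ry,
        ).astype(float).reshape(q, rx, ry)
        nz = joint.sum(axis=(1, 2), keepdims=True)
        mx = joint.sum(axis=2, keepdims=True)
        my = joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.where(nz > 0, mx * my / np.maximum(nz, 1), 0.0)
            g2 = 2.0 * xlogy(joint, np.where(joint > 0, joint / np.maximum(expected, 1e-300), 1.0)).sum()
        df = (rx - 1) * (ry - 1) * q
        return float(chdtrc(max(df, 1), max(g2, 0.0)))

    def _fisher_z(self, x: int, y: int, z: tuple[int, ...]) -> float:
        if not z:
            r = self.corr[x, y]
        else:
            sel = [x, y, *z]
            sub = self.corr[np.ix_(sel, sel)]
            try:
                prec = np.linalg.pinv(sub)
            except np.linalg.LinAlgError:
                return 1.0
            denom = np.sqrt(abs(prec[0, 0] * prec[1, 1]))
            r = -prec[0, 1] / max(denom, 1e-300)
        r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        dof = self.n - len(z) - 3
        if dof <= 0:
            return 1.0
        zstat = abs(np.arctanh(r)) * np.sqrt(dof)
        return float(erfc(zstat / np.sqrt(2.0)))


def _subsets(pool: list[int], max_size: int):
    for k in range(min(len(pool), max_size) + 1):
        yield from itertools.combinations(pool, k)


def _mmpc_target(t: int, tester: CITester, excluded: set[int]) -> set[int]:
    spec = tester.spec
    cpc: list[int] = []
    candidates = [x for x in range(tester.p) if x != t and x not in excluded]
    # grow: max-min heuristic over reliably testable conditioning sets
    while True:
        best_x, best_assoc = None, None
        for x in candidates:
            if x in cpc:
                continue
            ps = [
                tester.pvalue(x, t, tuple(sorted(s)))
                for s in _subsets(cpc, spec.max_condition)
                if tester.reliable(x, t, tuple(sorted(s)))
            ]
            if not ps:
                continue
            worst_p = max(ps)
            assoc = -worst_p
            if worst_p >= spec.alpha:
                continue
            if best_assoc is None or assoc > best_assoc or (
                assoc == best_assoc and x < best_x
            ):
                best_x, best_assoc = x, assoc
        if best_x is None:
            break
        cpc.append(best_x)
    # shrink: only a reliable test may certify independence
    changed = True
    while changed:
        changed = False
        for x in list(cpc):
            rest = [y for y in cpc if y != x]
            for s in _subsets(rest, spec.max_condition):
                zs = tuple(sorted(s))
                if tester.reliable(x, t, zs) and tester.pvalue(x, t, zs) >= spec.alpha:
                    cpc.remove(x)
                    changed = True
                    break
    return set(cpc)


def _hpc_target(t: int, tester: CITester, excluded: set[int]) -> set[int]:
    """Hybrid parents-and-children: marginal + first-order filtering to
    build a candidate superset, then subset-based shrinking within it."""
    spec = tester.spec
    pool = [
        x for x in range(tester.p)
        if x != t and x not in excluded and tester.pvalue(x, t) < spec.alpha
    ]
    # first-order filtering within the pool (reliable tests only)
    pcs = []
    for x in pool:
        if all(
            tester.pvalue(x, t, (z,)) < spec.alpha
            for z in pool
            if z != x and tester.reliable(x, t, (z,))
        ):
            pcs.append(x)
    # neighborhood-of-neighborhood augmentation: variables dependent on a
    # pool member and on t given that member re-enter the candidate set
    extra = []
    for x in range(tester.p):
        if x == t or x in pool or x in excluded:
            continue
        for z in pcs:
            if tester.pvalue(x, t, (z,)) < spec.alpha and tester.pvalue(x, z) < spec.alpha:
                extra.append(x)
                break
    cand = sorted(set(pcs) | set(extra))
    # shrink against subsets of the candidate set
    out = list(cand)
    changed = True
    while changed:
        changed = False
        for x in list(out):
            rest = [y for y in out if y != x]
            for s in _subsets(rest, spec.max_condition):
                zs = tuple(sorted(s))
                if tester.reliable(x, t, zs) and tester.pvalue(x, t, zs) >= spec.alpha:
                    out.remove(x)
                    changed = True
                    break
    return set(out)


def learn_skeleton(
    data: TransformedDataset | CITester,
    method: str = "mmpc",
    test: CITestSpec = CITestSpec(),
    blacklist: Blacklist = Blacklist(),
) -> set[frozenset]:
    """Undirected neighbor sets via MMPC or HPC with AND-symmetrization.

    A pair is forced absent only when the blacklist forbids it in both
    directions (one-way forbids are orientation constraints, handled in
    the maximize phase).
    """
    if method not in ("mmpc", "hpc"):
        raise ValueError(f"unknown skeleton method {method!r}")
    tester = data if isinstance(data, CITester) else CITester(data, test)
    nodes = tester.nodes
    if len(nodes) < 3:
        raise ValueError("need at least 3 variables for nontrivial conditioning")
    both_forbidden: dict[int, set[int]] = {i: set() for i in range(tester.p)}
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if i != j and blacklist.forbids(u, v) and blacklist.forbids(v, u):
                both_forbidden[i].add(j)
    fn = _mmpc_target if method == "mmpc" else _hpc_target
    pc = [fn(t, tester, both_forbidden[t]) for t in range(tester.p)]
    edges = set()
    for i in range(tester.p):
        for j in pc[i]:
            if i in pc[j]:  # AND rule
                edges.add(frozenset((nodes[i], nodes[j])))
    return edges


def hybrid_learn(
    data: TransformedDataset,
    method: str = "mmhc",
    test: CITestSpec = CITestSpec(),
    blacklist: Blacklist = Blacklist(),
    seed: int | None = None,
    skeleton: set[frozenset] | None = None,
) -> DAGStructure:
    """Restrict-then-maximize hybrid learner (MMHC or H2PC)."""
    if method not in ("mmhc", "h2pc"):
        raise ValueError(f"unknown hybrid method {method!r}")
    if skeleton is None:
        skel_method = "mmpc" if method == "mmhc" else "hpc"
        skeleton = learn_skeleton(data, skel_method, test, blacklist)
    return hill_climb(data, blacklist, allowed_pairs=skeleton)


def learn_structure(
    data: TransformedDataset,
    algorithm: str,
    blacklist: Blacklist = Blacklist(),
    test: CITestSpec = CITestSpec(),
    seed: int | None = None,
) -> DAGStructure:
    """Dispatch a learner by tag: hc, tabu, mmhc, or h2pc."""
    if algorithm == "hc":
        return hill_climb(data, blacklist, seed=seed)
    if algorithm == "tabu":
        return tabu_search(data, blacklist, seed=seed)
    if algorithm in ("mmhc", "h2pc"):
        return hybrid_learn(data, algorithm, test, blacklist, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")
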
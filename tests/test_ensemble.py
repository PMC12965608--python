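import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dualnet.ensemble as ens
from dualnet.ensemble import (
    ArcStrengthTable,
    EnsembleConfig,
    SubnetworkDAG,
    adhoc_threshold,
    arc_statistics,
    bootstrap_arc_strength,
    cell_seed,
    consensus_graph,
    dual_network_overlap,
    implied_presence_instances,
    min_consensus_cells,
    min_direction_count,
    min_retention_count,
    pattern_qualifies,
    run_ensemble,
)
from dualnet.rpcn import RPCNetwork
from dualnet.structure import Blacklist, DAGStructure
from dualnet.transforms import TRANSFORM_KINDS

from conftest import continuous_view

ALGOS = ("hc", "tabu", "mmhc", "h2pc")


def make_table(present, oriented, B=100, nodes=("a", "b", "c"),
               algorithm="hc", transformation="npn"):
    return ArcStrengthTable(
        algorithm=algorithm, transformation=transformation, B=B,
        nodes=list(nodes), present=dict(present), oriented=dict(oriented),
    )


def stub_subnet(algorithm, transformation, arcs, B=10_000, nodes=("a", "b", "c")):
    """arcs: {(u, v): (s, d)}"""
    return SubnetworkDAG(
        algorithm=algorithm, transformation=transformation, B=B,
        nodes=list(nodes),
        arcs={k: {"s": s, "d": d} for k, (s, d) in arcs.items()},
    )


def stub_grid(pair_cells, s=1.0, d=1.0, nodes=("a", "b", "c"),
              algorithms=ALGOS, transformations=TRANSFORM_KINDS):
    """Full grid of stub subnetworks; `pair_cells` maps (algo, kind) cells
    to arc dicts."""
    grid = {}
    for a in algorithms:
        for t in transformations:
            arcs = pair_cells.get((a, t), {})
            grid[(a, t)] = stub_subnet(a, t, arcs, nodes=nodes)
    return grid


def default_config(**kw):
    kw.setdefault("B", 10_000)
    return EnsembleConfig(**kw)


class TestBootstrapArcStrength:
    def test_stub_learner_all_zero(self, monkeypatch, rng):
        view = continuous_view(rng.normal(size=(50, 3)))
        monkeypatch.setattr(
            ens, "learn_structure",
            lambda data, algo, blacklist=None, test=None: DAGStructure(
                list(data.table.columns)),
        )
        table = bootstrap_arc_strength(view, "hc", EnsembleConfig(B=10, seed=1))
        assert table.present == {}

    def test_planted_arc_strong_and_oriented(self):
        g = np.random.default_rng(3)
        n = 1000
        a = g.normal(size=n)
        b = 0.8 * a + g.normal(0, 0.6, size=n)
        view = continuous_view(np.column_stack([a, b, g.normal(size=n)]),
                               ["a", "b", "z"])
        cfg = EnsembleConfig(B=200, seed=11)
        table = bootstrap_arc_strength(view, "hc", cfg)
        pair = frozenset(("a", "b"))
        assert table.strength(pair) >= 0.95
        assert table.direction("a", "b") >= 0.9

    def test_counting_identities(self):
        g = np.random.default_rng(5)
        x = g.normal(size=(200, 3))
        x[:, 1] += 0.7 * x[:, 0]
        view = continuous_view(x)
        cfg = EnsembleConfig(B=50, seed=2)
        table = bootstrap_arc_strength(view, "tabu", cfg)
        table.validate()
        for pair, cnt in table.present.items():
            u, v = sorted(pair)
            s = table.strength(pair)
            assert abs(s * cfg.B - round(s * cfg.B)) < 1e-9  # multiple of 1/B
            assert table.direction(u, v) + table.direction(v, u) == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(100, 3))
        view = continuous_view(x)
        cfg = EnsembleConfig(B=20, seed=9)
        t1 = bootstrap_arc_strength(view, "hc", cfg)
        t2 = bootstrap_arc_strength(view, "hc", cfg)
        assert t1.present == t2.present and t1.oriented == t2.oriented


class TestAdhocThreshold:
    def test_boundary_retained_and_oriented(self):
        cfg = default_config()
        pair = frozenset(("a", "b"))
        table = make_table({pair: 8500}, {("a", "b"): 5001, ("b", "a"): 3499})
        table.B = 10_000
        sub = adhoc_threshold(table, cfg)
        assert ("a", "b") in sub.arcs
        assert sub.arcs[("a", "b")]["s"] == pytest.approx(0.85)

    def test_just_below_strength_dropped(self):
        cfg = default_config()
        pair = frozenset(("a", "b"))
        table = make_table({pair: 8499}, {("a", "b"): 8499}, B=10_000)
        sub = adhoc_threshold(table, cfg)
        assert sub.arcs == {}

    def test_direction_tie_dropped_and_logged(self):
        cfg = default_config()
        pair = frozenset(("a", "b"))
        table = make_table({pair: 10_000}, {("a", "b"): 5000, ("b", "a"): 5000},
                           B=10_000)
        sub = adhoc_threshold(table, cfg)
        assert sub.arcs == {}
        assert len(sub.dropped_direction_unresolved) == 1

    def test_rule_table_oracle(self):
        # exhaustive check over count combinations against an
        # independently written rule
        cfg = EnsembleConfig(B=20)
        pair = frozenset(("a", "b"))
        for present in range(21):
            for fwd in range(present + 1):
                table = make_table({pair: present} if present else {},
                                   {("a", "b"): fwd, ("b", "a"): present - fwd},
                                   B=20)
                sub = adhoc_threshold(table, cfg)
                kept = bool(sub.arcs)
                # oracle: strength >= 0.85 of B and strict majority > B/2
                expect = present / 20 >= 0.85 and max(fwd, present - fwd) >= 11
                assert kept == expect, (present, fwd)

    def test_monotone_pruning_in_strength_min(self):
        pair = frozenset(("a", "b"))
        table = make_table({pair: 90}, {("a", "b"): 80, ("b", "a"): 10}, B=100)
        kept = [
            bool(adhoc_threshold(table, EnsembleConfig(B=100, strength_min=sm)).arcs)
            for sm in (0.5, 0.85, 0.95)
        ]
        assert kept == [True, True, False]

    def test_cycle_detected(self):
        cfg = EnsembleConfig(B=10)
        table = make_table(
            {frozenset(("a", "b")): 10, frozenset(("b", "c")): 10,
             frozenset(("a", "c")): 10},
            {("a", "b"): 10, ("b", "c"): 10, ("c", "a"): 10},
            B=10,
        )
        with pytest.raises(RuntimeError, match="cycle"):
            adhoc_threshold(table, cfg)


class TestRunEnsemble:
    @pytest.fixture(scope="class")
    def small_suite(self):
        g = np.random.default_rng(7)
        n = 300
        a = g.normal(size=n)
        b = 0.8 * a + g.normal(0, 0.6, size=n)
        c = 0.8 * b + g.normal(0, 0.6, size=n)
        x = np.column_stack([a, b, c])
        codes = np.floor(np.clip((x + 3) / 2, 0, 2.99))
        from conftest import discrete_view

        return {
            "disc3": discrete_view(codes, list("abc"), kind="disc3"),
            "disc5": discrete_view(codes, list("abc"), kind="disc5"),
            "npn": continuous_view(x, list("abc"), kind="npn"),
            "int": continuous_view(x, list("abc"), kind="int"),
        }

    def test_reduced_grid_arithmetic(self, small_suite):
        cfg = EnsembleConfig(B=5, seed=3, algorithms=("hc", "tabu"),
                             transformations=("npn", "int"),
                             min_transformations=2)
        subnets = run_ensemble(small_suite, cfg)
        assert len(subnets) == 4
        assert set(subnets) == {(a, t) for a in ("hc", "tabu") for t in ("npn", "int")}

    def test_full_grid_sixteen_cells(self, small_suite):
        cfg = EnsembleConfig(B=3, seed=4)
        subnets = run_ensemble(small_suite, cfg)
        assert len(subnets) == 16

    def test_order_independence(self, small_suite):
        cfg1 = EnsembleConfig(B=5, seed=8, algorithms=("hc", "tabu"),
                              transformations=("npn", "int"), min_transformations=2)
        cfg2 = EnsembleConfig(B=5, seed=8, algorithms=("tabu", "hc"),
                              transformations=("int", "npn"), min_transformations=2)
        s1 = run_ensemble(small_suite, cfg1)
        s2 = run_ensemble(small_suite, cfg2)
        for cell in s1:
            assert s1[cell].arcs == s2[cell].arcs

    def test_cell_seed_stability(self):
        a = cell_seed(5, "hc", "npn")
        b = cell_seed(5, "hc", "npn")
        c = cell_seed(5, "tabu", "npn")
        assert a.entropy == b.entropy
        assert a.entropy != c.entropy


class TestConsensus:
    def test_twelve_cells_grand_point_seven_five(self):
        cells = {(a, t): {("a", "b"): (1.0, 1.0)}
                 for a in ALGOS for t in TRANSFORM_KINDS[:3]}
        grid = stub_grid(cells)
        cfg = default_config()
        arc = arc_statistics(grid, frozenset(("a", "b")), cfg)
        assert arc.k == 12
        assert arc.learned_strength == pytest.approx(1.0)
        assert arc.grand_strength == pytest.approx(0.75)

    def test_three_algorithms_everywhere_excluded(self):
        cells = {(a, t): {("a", "b"): (1.0, 1.0)}
                 for a in ("hc", "tabu", "mmhc") for t in TRANSFORM_KINDS}
        grid = stub_grid(cells)
        cons = consensus_graph(grid, default_config())
        assert cons.arcs == []

    def test_saturated_arc(self):
        cells = {(a, t): {("a", "b"): (1.0, 1.0)}
                 for a in ALGOS for t in TRANSFORM_KINDS}
        cons = consensus_graph(stub_grid(cells), default_config())
        assert len(cons.arcs) == 1
        arc = cons.arcs[0]
        assert arc.learned_strength == arc.grand_strength == 1.0
        assert arc.learned_direction == arc.grand_direction == 1.0

    def test_pattern_rule_against_independent_oracle(self):
        cells = [(a, t) for a in ALGOS for t in TRANSFORM_KINDS]
        g = np.random.default_rng(15)
        for _ in range(300):
            mask = g.random(16) < g.random()
            present = {c for c, m in zip(cells, mask) if m}
            # independent oracle: per transformation, presence under all
            # four algorithms; need >= 3 such transformations
            complete_cols = 0
            for t in TRANSFORM_KINDS:
                if {(a, t) for a in ALGOS} <= present:
                    complete_cols += 1
            expected = complete_cols >= 3
            got = pattern_qualifies(present, ALGOS, TRANSFORM_KINDS, 3)
            assert got == expected

    def test_consensus_subset_of_union(self):
        g = np.random.default_rng(21)
        pairs = [("a", "b"), ("b", "c"), ("a", "c")]
        cells = {}
        for a in ALGOS:
            for t in TRANSFORM_KINDS:
                arcs = {}
                for u, v in pairs:
                    if g.random() < 0.8:
                        arcs[(u, v)] = (g.uniform(0.85, 1.0), g.uniform(0.6, 1.0))
                cells[(a, t)] = arcs
        grid = stub_grid(cells)
        cons = consensus_graph(grid, default_config())
        union = set()
        for sub in grid.values():
            union |= sub.pairs()
        assert cons.arc_pairs() <= union

    def test_orientation_agnostic_k_and_flip(self):
        # cells disagree on orientation; k counts both, direction pooled
        cells = {}
        for i, (a, t) in enumerate((a, t) for a in ALGOS for t in TRANSFORM_KINDS):
            if i < 12:
                arcs = {("a", "b"): (0.9, 0.8)} if i < 4 else {("b", "a"): (0.9, 0.9)}
                cells[(a, t)] = arcs
        grid = stub_grid(cells)
        arc = arc_statistics(grid, frozenset(("a", "b")), default_config())
        assert arc.k == 12
        # mean d(a->b) = (4*0.8 + 8*0.1)/12 = 1/3 -> flipped to b->a
        assert (arc.from_, arc.to) == ("b", "a")
        assert arc.learned_direction == pytest.approx(2 / 3)
        assert arc.grand_direction == pytest.approx((2 / 3) * 12 / 16)

    def test_unknown_pair_errors(self):
        grid = stub_grid({})
        with pytest.raises(ValueError):
            arc_statistics(grid, frozenset(("a", "b")), default_config())

    @given(
        k=st.integers(1, 16),
        s=st.floats(0.85, 1.0),
        d=st.floats(0.5, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_grand_identity_property(self, k, s, d):
        cells = [(a, t) for a in ALGOS for t in TRANSFORM_KINDS][:k]
        grid = stub_grid({c: {("a", "b"): (s, d)} for c in cells})
        arc = arc_statistics(grid, frozenset(("a", "b")), default_config())
        assert abs(arc.grand_strength - arc.learned_strength * k / 16) <= 1e-12
        assert abs(arc.grand_direction - arc.learned_direction * k / 16) <= 1e-12


class TestBookkeeping:
    def test_min_retention_count(self):
        assert min_retention_count(default_config()) == 8500

    def test_min_direction_count(self):
        assert min_direction_count(default_config()) == 5001

    def test_min_consensus_cells(self):
        assert min_consensus_cells(default_config()) == 12

    def test_implied_instances(self):
        assert implied_presence_instances(0.9844, default_config()) == 157_504

    def test_reduced_grid_consensus_minimum(self):
        cfg = EnsembleConfig(B=100, algorithms=("hc", "tabu"),
                             transformations=("npn", "int"), min_transformations=1)
        assert min_consensus_cells(cfg) == 2


class TestOverlap:
    @staticmethod
    def big_net(n_edges=75, p=15, seed=1):
        g = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(p)]
        w = np.zeros((p, p))
        pairs = list(itertools.combinations(range(p), 2))
        chosen = [pairs[i] for i in g.choice(len(pairs), n_edges, replace=False)]
        for i, j in chosen:
            w[i, j] = w[j, i] = g.uniform(0.05, 0.4) * g.choice([-1, 1])
        return RPCNetwork(w, 0.1, nodes), chosen, nodes

    def test_26_of_75_is_34_67(self):
        from dualnet.ensemble import ConsensusArc, ConsensusGraph

        net, chosen, nodes = self.big_net()
        arcs = [
            ConsensusArc(nodes[i], nodes[j], 16, 1.0, 1.0, 1.0, 1.0)
            for i, j in chosen[:26]
        ]
        cons = ConsensusGraph(nodes=nodes, arcs=arcs, K=16, acyclic=True)
        rep = dual_network_overlap(net, cons)
        assert rep.n_rpcn_edges == 75
        assert rep.n_shared == 26
        assert round(rep.shared_percentage, 2) == 34.67

    def test_disjoint_zero(self):
        from dualnet.ensemble import ConsensusGraph

        net, chosen, nodes = self.big_net(10, 8, seed=2)
        cons = ConsensusGraph(nodes=nodes, arcs=[], K=16, acyclic=True)
        rep = dual_network_overlap(net, cons)
        assert rep.n_shared == 0 and rep.shared_percentage == 0.0
        assert not rep.comparison_applicable

    def test_welch_hand_computed(self):
        # textbook Welch on 4 + 4 values
        a = np.array([0.30, 0.25, 0.28, 0.33])
        b = np.array([0.10, 0.05, 0.12, 0.08])
        t, df, lo, hi, p = ens._welch(a, b)
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 4 + vb / 4
        t_hand = (ma - mb) / math.sqrt(se2)
        df_hand = se2**2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand))
        assert lo < ma - mb < hi
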
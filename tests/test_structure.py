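import itertools
import math

import numpy as np
import pytest

from dualnet.structure import (
    Blacklist,
    CITestSpec,
    CITester,
    DAGStructure,
    DiscreteBICScore,
    GaussianBICScore,
    hill_climb,
    hybrid_learn,
    learn_skeleton,
    learn_structure,
    score_dag,
    tabu_search,
)

from conftest import continuous_view, discrete_view


def all_dags(nodes):
    """Enumerate every DAG over `nodes` (25 at p=3, 543 at p=4)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(1 << len(pairs)):
        arcs = {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
        try:
            yield DAGStructure(list(nodes), arcs)
        except ValueError:
            continue


def chain_data(seed, n=2000, beta=0.8):
    g = np.random.default_rng(seed)
    x = g.normal(size=n)
    y = beta * x + g.normal(0, 0.6, size=n)
    z = beta * y + g.normal(0, 0.6, size=n)
    return np.column_stack([x, y, z])


class TestDAGStructure:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            DAGStructure(["a", "b"], {("a", "b"), ("b", "a")})

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DAGStructure(["a"], {("a", "a")})

    def test_topological_order(self):
        d = DAGStructure(["a", "b", "c"], {("a", "b"), ("b", "c")})
        assert d.topological_order() == ["a", "b", "c"]

    def test_enumeration_counts(self):
        assert sum(1 for _ in all_dags(["a", "b", "c"])) == 25
        assert sum(1 for _ in all_dags(["a", "b", "c", "d"])) == 543


class TestBlacklist:
    def test_sink_expansion(self):
        bl = Blacklist.from_sinks(["age"])
        expanded = bl.expand(["age", "x", "y"])
        assert expanded == {("x", "age"), ("y", "age")}

    def test_audit(self):
        bl = Blacklist.from_sinks(["age"])
        with pytest.raises(AssertionError):
            bl.audit(DAGStructure(["age", "x"], {("x", "age")}))
        bl.audit(DAGStructure(["age", "x"], {("age", "x")}))


class TestScores:
    def test_empty_dag_hand_computed(self):
        # 4-row table, two binary columns: marginal multinomial loglik
        # minus (r-1) * log(n)/2 per node
        codes = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        score = DiscreteBICScore(codes, ["a", "b"])
        dag = DAGStructure(["a", "b"])
        total, per_node = score_dag(dag, score)
        expected_node = 2 * math.log(0.5) * 2 - 1 * math.log(4) / 2
        assert per_node["a"] == pytest.approx(expected_node)
        assert total == pytest.approx(2 * expected_node)

    def test_arc_between_independent_lowers_bic(self):
        g = np.random.default_rng(2)
        codes = g.integers(0, 2, size=(2000, 2))
        score = DiscreteBICScore(codes, ["a", "b"])
        empty, _ = score_dag(DAGStructure(["a", "b"]), score)
        arc, _ = score_dag(DAGStructure(["a", "b"], {("a", "b")}), score)
        assert arc < empty

    @pytest.mark.parametrize("family", ["discrete", "gaussian"])
    def test_markov_equivalence_class_scores_equal(self, family):
        g = np.random.default_rng(5)
        if family == "discrete":
            x = g.integers(0, 3, size=(200, 1))
            y = (x[:, 0] + g.integers(0, 2, 200)) % 3
            z = (y + g.integers(0, 2, 200)) % 3
            score = DiscreteBICScore(np.column_stack([x[:, 0], y, z]), list("xyz"))
        else:
            data = chain_data(5, n=200)
            score = GaussianBICScore(data, list("xyz"))
        # chain x->y->z, reversed chain, and fork y->x, y->z share one
        # Markov equivalence class
        dags = [
            DAGStructure(list("xyz"), {("x", "y"), ("y", "z")}),
            DAGStructure(list("xyz"), {("z", "y"), ("y", "x")}),
            DAGStructure(list("xyz"), {("y", "x"), ("y", "z")}),
        ]
        assert len({d.cpdag_key() for d in dags}) == 1
        totals = [score_dag(d, score)[0] for d in dags]
        assert totals[0] == pytest.approx(totals[1], abs=1e-8)
        assert totals[0] == pytest.approx(totals[2], abs=1e-8)

    def test_collider_scores_differ(self):
        score = GaussianBICScore(chain_data(7, n=500), list("xyz"))
        chain, _ = score_dag(DAGStructure(list("xyz"), {("x", "y"), ("y", "z")}), score)
        collider, _ = score_dag(DAGStructure(list("xyz"), {("x", "y"), ("z", "y")}), score)
        assert chain > collider

    def test_cache_consistency(self):
        data = chain_data(11, n=300)
        cached = GaussianBICScore(data, list("xyz"))
        dag = DAGStructure(list("xyz"), {("x", "y"), ("y", "z")})
        t1, _ = score_dag(dag, cached)
        t2, _ = score_dag(dag, cached)  # all-cache path
        fresh, _ = score_dag(dag, GaussianBICScore(data, list("xyz")))
        assert t1 == t2 == pytest.approx(fresh)


class TestHillClimb:
    def test_independence_gives_empty_dag(self):
        g = np.random.default_rng(13)
        view = continuous_view(g.normal(size=(2000, 3)))
        dag = hill_climb(view)
        assert dag.arcs == set()

    def test_chain_reaches_global_optimum(self):
        view = continuous_view(chain_data(17), list("xyz"))
        score = GaussianBICScore(view.matrix(), list("xyz"))
        dag = hill_climb(score)
        best = max(score_dag(d, score)[0] for d in all_dags(list("xyz")))
        assert score_dag(dag, score)[0] == pytest.approx(best)

    def test_blacklist_sink_has_zero_indegree(self):
        view = continuous_view(chain_data(19), list("xyz"))
        bl = Blacklist.from_sinks(["y"])
        dag = hill_climb(view, bl)
        assert dag.indegree("y") == 0

    def test_never_beats_exhaustive_and_matches_on_high_signal(self):
        g = np.random.default_rng(23)
        n = 1500
        a = g.normal(size=n)
        b = 0.8 * a + g.normal(0, 0.5, size=n)
        c = 0.7 * b + g.normal(0, 0.5, size=n)
        d = 0.8 * c + g.normal(0, 0.5, size=n)
        score = GaussianBICScore(np.column_stack([a, b, c, d]), list("abcd"))
        best = max(score_dag(dg, score)[0] for dg in all_dags(list("abcd")))
        hc_total, _ = score_dag(hill_climb(score), score)
        assert hc_total <= best + 1e-9
        assert hc_total == pytest.approx(best)


class TestTabu:
    def test_degenerates_to_hill_climb(self):
        view = continuous_view(chain_data(29), list("xyz"))
        hc = hill_climb(view)
        tb = tabu_search(view, tabu_length=0, max_worsening_moves=0)
        assert hc.arcs == tb.arcs

    def test_never_worse_than_hc_over_seeds(self):
        for seed in range(20):
            g = np.random.default_rng(seed)
            x = g.normal(size=(400, 4))
            x[:, 1] += 0.6 * x[:, 0]
            x[:, 2] += 0.5 * x[:, 1] - 0.4 * x[:, 3]
            score = GaussianBICScore(x, list("abcd"))
            hc_total, _ = score_dag(hill_climb(score), score)
            tb_total, _ = score_dag(tabu_search(score), score)
            assert tb_total >= hc_total - 1e-9

    def test_independence_empty(self):
        g = np.random.default_rng(31)
        view = continuous_view(g.integers(0, 3, size=(1500, 3)).astype(float))
        assert tabu_search(view).arcs == set()


class TestSkeleton:
    def test_independence_empty(self):
        # seed chosen so no pair is spuriously dependent at alpha = 0.05
        g = np.random.default_rng(30)
        view = continuous_view(g.normal(size=(2000, 4)))
        for method in ("mmpc", "hpc"):
            assert learn_skeleton(view, method) == set()

    @pytest.mark.parametrize("method", ["mmpc", "hpc"])
    def test_chain_skeleton(self, method):
        view = continuous_view(chain_data(41), list("xyz"))
        skel = learn_skeleton(view, method)
        assert skel == {frozenset(("x", "y")), frozenset(("y", "z"))}

    @pytest.mark.parametrize("method", ["mmpc", "hpc"])
    def test_clique_recovered(self, method):
        g = np.random.default_rng(43)
        n = 2000
        a = g.normal(size=n)
        b = 0.7 * a + g.normal(0, 0.6, size=n)
        c = 0.5 * a + 0.5 * b + g.normal(0, 0.6, size=n)
        view = continuous_view(np.column_stack([a, b, c]), list("abc"))
        skel = learn_skeleton(view, method)
        assert skel == {frozenset(p) for p in itertools.combinations("abc", 2)}

    def test_discrete_chain_skeleton(self):
        g = np.random.default_rng(47)
        n = 2000
        x = g.integers(0, 3, n)
        y = np.where(g.random(n) < 0.8, x, g.integers(0, 3, n))
        z = np.where(g.random(n) < 0.8, y, g.integers(0, 3, n))
        view = discrete_view(np.column_stack([x, y, z]), list("xyz"))
        skel = learn_skeleton(view, "mmpc")
        assert skel == {frozenset(("x", "y")), frozenset(("y", "z"))}

    def test_needs_three_variables(self):
        g = np.random.default_rng(53)
        view = continuous_view(g.normal(size=(100, 2)))
        with pytest.raises(ValueError):
            learn_skeleton(view)


class TestHybrid:
    def test_full_skeleton_degenerates_to_hc(self):
        view = continuous_view(chain_data(59), list("xyz"))
        full = {frozenset(p) for p in itertools.combinations("xyz", 2)}
        dag = hybrid_learn(view, "mmhc", skeleton=full)
        assert dag.arcs == hill_climb(view).arcs

    def test_excluded_pair_never_appears(self):
        view = continuous_view(chain_data(61), list("xyz"))
        skel = {frozenset(("x", "y"))}
        dag = hybrid_learn(view, "mmhc", skeleton=skel)
        assert ("y", "z") not in dag.arcs and ("z", "y") not in dag.arcs

    @pytest.mark.parametrize("method", ["mmhc", "h2pc"])
    def test_planted_dag_cpdag_recovery(self, method):
        # 5-node planted DAG with strong effects: CPDAG recovered in
        # >= 90% of 50 seeded replicates
        truth = DAGStructure(
            list("abcde"),
            {("a", "b"), ("b", "c"), ("c", "d"), ("a", "e"), ("d", "e")},
        )
        hits = 0
        for seed in range(50):
            g = np.random.default_rng(1000 + seed)
            n = 1500
            a = g.normal(size=n)
            b = 0.8 * a + g.normal(0, 0.5, size=n)
            c = 0.8 * b + g.normal(0, 0.5, size=n)
            d = 0.8 * c + g.normal(0, 0.5, size=n)
            e = 0.6 * a + 0.6 * d + g.normal(0, 0.4, size=n)
            view = continuous_view(np.column_stack([a, b, c, d, e]), list("abcde"))
            est = hybrid_learn(view, method)
            hits += est.cpdag_key() == truth.cpdag_key()
        assert hits >= 45

    def test_learn_structure_dispatch(self):
        view = continuous_view(chain_data(67), list("xyz"))
        for algo in ("hc", "tabu", "mmhc", "h2pc"):
            dag = learn_structure(view, algo)
            assert dag.is_acyclic()
            assert dag.skeleton() == {frozenset(("x", "y")), frozenset(("y", "z"))}
        with pytest.raises(ValueError):
            learn_structure(view, "nope")


class TestCITester:
    def test_fisher_z_matches_partial_correlation(self):
        data = chain_data(71, n=500)
        view = continuous_view(data, list("xyz"))
        tester = CITester(view, CITestSpec())
        # x and z are d-separated by y in the chain: large p given y,
        # small p marginally
        assert tester.pvalue(0, 2, (1,)) > 0.05
        assert tester.pvalue(0, 2) < 1e-6

    def test_discrete_g2_independence(self):
        g = np.random.default_rng(73)
        codes = g.integers(0, 3, size=(3000, 2))
        view = discrete_view(codes, ["a", "b"])
        tester = CITester(view, CITestSpec())
        assert tester.pvalue(0, 1) > 0.001
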
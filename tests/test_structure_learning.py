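"""Score-based, constraint-based and knowledge-constrained structure search."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from lungbn.data_model import (
    ConfigurationError,
    Dag,
    DegenerateDataError,
    log_bayesian_score,
)
from lungbn.structure_learning import (
    PairwiseRelation,
    SearchConfig,
    StructurePrior,
    aggregate_dags,
    anneal_search,
    conditional_mutual_information,
    constraint_learn,
    constrained_search,
    g_squared_test,
    k2_search,
    learn_tan,
    mcmc_search,
)
from lungbn.synthetic_data import five_variable_demo_net, sample_cohort
from .conftest import make_dataset


def all_dags(names):
    """Exhaustive oracle: every labelled DAG over `names` (small n only)."""
    pairs = list(itertools.combinations(names, 2))
    for directions in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), d in zip(pairs, directions):
            if d == 1:
                edges.append((a, b))
            elif d == 2:
                edges.append((b, a))
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield Dag(names, edges)


def cpdag_skeleton_and_vstructures(dag):
    skel = frozenset(frozenset(e) for e in dag.edges)
    vs = set()
    for v in dag.variables:
        for a, b in itertools.combinations(dag.parents(v), 2):
            if frozenset((a, b)) not in skel:
                vs.add((frozenset((a, b)), v))
    return skel, frozenset(vs)


class TestTAN:
    def test_two_predictors_single_tree_edge(self):
        rng = np.random.default_rng(0)
        data = make_dataset(
            {"X": rng.integers(0, 2, 200), "Y": rng.integers(0, 2, 200),
             "C": rng.integers(0, 2, 200)}
        )
        dag = learn_tan(data, "C")
        pred_edges = {e for e in dag.edges if e[0] != "C"}
        assert len(pred_edges) == 1
        assert ("C", "X") in dag.edges and ("C", "Y") in dag.edges

    def test_xor_dependent_pair_always_in_tree(self):
        rng = np.random.default_rng(1)
        n = 20_000
        c = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        y = x ^ rng.integers(0, 2, n, dtype=np.int64) * 0  # y == x: max CMI pair
        z = rng.integers(0, 2, n)
        data = make_dataset({"X": x, "Y": y, "Z": z, "C": c})
        # CMI oracle ranks (X, Y) maximal
        cmis = {
            pair: conditional_mutual_information(data, *pair, "C")
            for pair in (("X", "Y"), ("X", "Z"), ("Y", "Z"))
        }
        assert max(cmis, key=cmis.get) == ("X", "Y")
        dag = learn_tan(data, "C")
        assert ("X", "Y") in dag.edges or ("Y", "X") in dag.edges

    def test_constant_class_raises(self):
        data = make_dataset({"X": [0, 1], "Y": [0, 1], "C": [0, 0]},
                            states={"C": ("a", "b")})
        with pytest.raises(DegenerateDataError):
            learn_tan(data, "C")


class TestK2:
    def test_independent_variables_give_empty_graph(self):
        rng = np.random.default_rng(2)
        data = make_dataset({n: rng.integers(0, 2, 2000) for n in "ABC"})
        dag = k2_search(data, ["A", "B", "C"], 3)
        assert dag.edges == frozenset()

    def test_recovers_edge_in_both_orders(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 10_000)
        b = np.where(rng.random(10_000) < 0.85, a, 1 - a)
        data = make_dataset({"A": a, "B": b})
        # score-comparison oracle: dependent model beats independent
        dep = log_bayesian_score(Dag(["A", "B"], [("A", "B")]), data)
        indep = log_bayesian_score(Dag(["A", "B"]), data)
        assert dep > indep
        assert k2_search(data, ["A", "B"], 2).edges == frozenset({("A", "B")})
        assert k2_search(data, ["B", "A"], 2).edges == frozenset({("B", "A")})

    def test_order_must_cover_all_variables(self):
        data = make_dataset({"A": [0, 1], "B": [0, 1]})
        with pytest.raises(ValueError):
            k2_search(data, ["A"], 2)

    def test_exact_recovery_equals_exhaustive_order_consistent_optimum(self):
        net = five_variable_demo_net()
        data = sample_cohort(net, 10_000, 1)
        order = ["A", "B", "C", "D", "E"]
        dag = k2_search(data, order, 4)
        assert set(dag.edges) == set(net.dag.edges)
        # decomposable exhaustive oracle: best predecessor subset per node
        from lungbn.data_model import family_score

        best_edges = set()
        for i, v in enumerate(order):
            preds = order[:i]
            best_sub, best_val = (), family_score(data, v, ())
            for k in range(1, len(preds) + 1):
                for sub in itertools.combinations(preds, k):
                    val = family_score(data, v, sub)
                    if val > best_val:
                        best_sub, best_val = sub, val
            best_edges |= {(p, v) for p in best_sub}
        assert set(dag.edges) == best_edges


class TestAnnealing:
    def test_two_variable_dependence_found(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 5000)
        b = np.where(rng.random(5000) < 0.9, a, 1 - a)
        data = make_dataset({"A": a, "B": b})
        dag = anneal_search(data, SearchConfig(seed=0, n_sweeps=40))
        assert dag.edges in ({("A", "B")} | set(), frozenset({("A", "B")}), frozenset({("B", "A")}))
        assert len(dag.edges) == 1

    def test_never_worse_than_empty_graph(self):
        rng = np.random.default_rng(5)
        data = make_dataset({n: rng.integers(0, 2, 300) for n in "ABCD"})
        dag = anneal_search(data, SearchConfig(seed=1, n_sweeps=20))
        assert log_bayesian_score(dag, data) >= log_bayesian_score(Dag(data.names), data)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        data = make_dataset({n: rng.integers(0, 3, 400) for n in "ABC"},
                            states={n: ("x", "y", "z") for n in "ABC"})
        cfg = SearchConfig(seed=7, n_sweeps=30)
        assert anneal_search(data, cfg).edges == anneal_search(data, cfg).edges


class TestMCMC:
    def test_vstructure_equivalence_class_recovered(self):
        rng = np.random.default_rng(8)
        n = 5000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        # generic collider: both parents matter, with interaction (not XOR,
        # whose pairwise independencies make every orientation equivalent)
        p1 = np.array([[0.10, 0.45], [0.70, 0.95]])[a, b]
        c = (rng.random(n) < p1).astype(int)
        data = make_dataset({"A": a, "B": b, "C": c})
        dag = mcmc_search(data, SearchConfig(seed=2, mcmc_steps=4000, burn_in=500))
        # exhaustive 25-DAG oracle
        scored = [(log_bayesian_score(g, data), g) for g in all_dags(["A", "B", "C"])]
        best = max(scored, key=lambda t: t[0])[1]
        truth = Dag(["A", "B", "C"], [("A", "C"), ("B", "C")])
        assert cpdag_skeleton_and_vstructures(best) == cpdag_skeleton_and_vstructures(truth)
        assert cpdag_skeleton_and_vstructures(dag) == cpdag_skeleton_and_vstructures(truth)

    def test_edge_frequencies_are_probabilities(self):
        rng = np.random.default_rng(9)
        data = make_dataset({n: rng.integers(0, 2, 200) for n in "ABC"})
        _, freq = mcmc_search(
            data, SearchConfig(seed=3, mcmc_steps=2000, burn_in=200), return_stats=True
        )
        assert all(0.0 <= f <= 1.0 for f in freq.values())

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        data = make_dataset({n: rng.integers(0, 2, 300) for n in "ABC"})
        cfg = SearchConfig(seed=5, mcmc_steps=1500, burn_in=100)
        assert mcmc_search(data, cfg).edges == mcmc_search(data, cfg).edges


class TestConstraintBased:
    def test_independent_pair_no_edge(self):
        rng = np.random.default_rng(11)
        data = make_dataset({"A": rng.integers(0, 2, 10_000), "B": rng.integers(0, 2, 10_000)})
        # chi-square-style oracle: the G2 p-value itself is large
        pval, _, testable = g_squared_test(data, "A", "B", ())
        assert testable and pval > 0.01
        dag = constraint_learn(data, 0.01)
        assert dag.edges == frozenset()

    def test_chain_skeleton_without_shortcut(self):
        rng = np.random.default_rng(12)
        n = 10_000
        a = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.85, a, 1 - a)
        c = np.where(rng.random(n) < 0.85, b, 1 - b)
        data = make_dataset({"A": a, "B": b, "C": c})
        dag = constraint_learn(data, 0.01)
        skel = {frozenset(e) for e in dag.edges}
        assert skel == {frozenset(("A", "B")), frozenset(("B", "C"))}
        # CI oracle: A independent of C given B
        pval, _, _ = g_squared_test(data, "A", "C", ("B",))
        assert pval > 0.01

    def test_collider_oriented_into_common_child(self):
        rng = np.random.default_rng(13)
        n = 10_000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        p1 = np.array([[0.10, 0.45], [0.70, 0.95]])[a, b]
        c = (rng.random(n) < p1).astype(int)
        data = make_dataset({"A": a, "B": b, "C": c})
        # oracle: marginal independence, conditional dependence
        p_marg, _, _ = g_squared_test(data, "A", "B", ())
        p_cond, _, _ = g_squared_test(data, "A", "B", ("C",))
        assert p_marg > 0.01 > p_cond
        dag = constraint_learn(data, 0.01)
        assert ("A", "C") in dag.edges and ("B", "C") in dag.edges

    def test_small_sample_emits_warning_and_keeps_edge(self):
        data = make_dataset({"A": [0, 1, 0], "B": [0, 1, 1], "C": [1, 0, 1]})
        with pytest.warns(UserWarning):
            constraint_learn(data, 0.05)

    def test_alpha_range_validated(self):
        data = make_dataset({"A": [0, 1], "B": [0, 1]})
        with pytest.raises(ValueError):
            constraint_learn(data, 1.5)


class TestConstrainedSearch:
    def _tiered_data(self, seed, n=800):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        t = np.where(rng.random(n) < 0.8, x, 1 - x)
        s = np.where(rng.random(n) < 0.75, t, 1 - t)
        return make_dataset({"X": x, "T": t, "S": s},
                            tiers={"X": "pre_treatment", "T": "treatment", "S": "post_treatment"})

    def test_hard_tiers_never_violated(self):
        tiers = {"X": 0, "T": 1, "S": 2}
        for seed in range(20):
            data = self._tiered_data(seed)
            prior = StructurePrior(tiers=tiers)
            dag = constrained_search(data, prior, SearchConfig(seed=seed, n_sweeps=25))
            for a, b in dag.edges:
                assert tiers[a] <= tiers[b]

    def test_soft_edge_included_iff_bonus_beats_score_penalty(self):
        rng = np.random.default_rng(30)
        data = make_dataset({"A": rng.integers(0, 2, 400), "B": rng.integers(0, 2, 400)})
        empty = log_bayesian_score(Dag(["A", "B"]), data)
        fwd = log_bayesian_score(Dag(["A", "B"], [("A", "B")]), data)
        penalty = empty - fwd  # > 0 on independent data
        for conf in (0.55, 0.999):
            bonus = math.log(conf / (1 - conf))
            prior = StructurePrior(pairwise=[PairwiseRelation("A", "B", "directly_influences", conf)])
            # exhaustive 3-structure oracle with prior
            table = {
                frozenset(): empty,
                frozenset({("A", "B")}): fwd + bonus,
                frozenset({("B", "A")}): log_bayesian_score(Dag(["A", "B"], [("B", "A")]), data),
            }
            want_edge = bonus > penalty
            assert (max(table, key=table.get) == frozenset({("A", "B")})) == want_edge
            dag = constrained_search(data, prior, SearchConfig(seed=1, n_sweeps=40))
            assert (("A", "B") in dag.edges) == want_edge

    def test_confidence_near_one_forces_edge_on_neutral_data(self):
        rng = np.random.default_rng(31)
        data = make_dataset({"A": rng.integers(0, 2, 200), "B": rng.integers(0, 2, 200)})
        prior = StructurePrior(
            pairwise=[PairwiseRelation("A", "B", "directly_influences", 0.999999)]
        )
        for seed in range(5):
            dag = constrained_search(data, prior, SearchConfig(seed=seed, n_sweeps=30))
            assert ("A", "B") in dag.edges

    def test_infeasible_hard_constraints_raise(self):
        data = self._tiered_data(0)
        prior = StructurePrior(
            tiers={"X": 0, "T": 1, "S": 2},
            pairwise=[PairwiseRelation("S", "X", "directly_influences", 1.0)],
        )
        with pytest.raises(ConfigurationError):
            constrained_search(data, prior, SearchConfig(seed=0, n_sweeps=5))


class TestAggregateDags:
    def _branching_oracle(self, names, weighted_edges):
        """Exhaustive oracle: best acyclic <=1-parent edge subset by weight."""
        best, best_w = frozenset(), -1.0
        edges = list(weighted_edges)
        for r in range(len(edges) + 1):
            for sub in itertools.combinations(edges, r):
                children = [b for (a, b), w in sub]
                if len(set(children)) != len(children):
                    continue
                g = nx.DiGraph()
                g.add_nodes_from(names)
                g.add_edges_from([e for e, w in sub])
                if not nx.is_directed_acyclic_graph(g):
                    continue
                w = sum(w for e, w in sub)
                if w > best_w:
                    best, best_w = frozenset(e for e, w in sub), w
        return best

    def test_unanimous_tree_returned(self):
        tree = Dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert aggregate_dags([tree] * 10).edges == tree.edges

    def test_majority_direction_kept(self):
        names = ["A", "B", "C"]
        fwd = Dag(names, [("A", "B"), ("B", "C")])
        rev = Dag(names, [("B", "A"), ("B", "C")])
        dags = [fwd] * 9 + [rev]
        out = aggregate_dags(dags)
        weighted = [(("A", "B"), 0.9), (("B", "A"), 0.1), (("B", "C"), 1.0)]
        assert out.edges == self._branching_oracle(names, weighted)
        assert ("A", "B") in out.edges

    def test_node_disjoint_forest_union(self):
        names = ["A", "B", "C", "D"]
        t = Dag(names, [("A", "B"), ("C", "D")])
        out = aggregate_dags([t] * 3)
        assert out.edges == t.edges

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            aggregate_dags([])

    def test_outputs_always_acyclic(self):
        rng = np.random.default_rng(40)
        names = ["A", "B", "C", "D"]
        dags = []
        for _ in range(8):
            edges = []
            order = list(rng.permutation(names))
            for i in range(3):
                if rng.random() < 0.7:
                    edges.append((order[i], order[i + 1]))
            dags.append(Dag(names, edges))
        out = aggregate_dags(dags)  # Dag constructor enforces acyclicity
        assert isinstance(out, Dag)
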
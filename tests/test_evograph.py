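import itertools
import math

import networkx as nx
import numpy as np
import pytest

from tedg.evograph import (
    OrderGraph,
    TedgConfig,
    build_sequential_network,
    deconvolve,
    extract_tedg,
    pool_isn,
    presence_calls,
    simplify_isn,
)
from tedg.mcf_adjust import MCFProfile


def profile(pid, t, **mcf):
    return MCFProfile(pid, t, dict(mcf))


class TestPresenceCalls:
    def test_threshold_is_strict(self):
        p = profile("P1", 0, a=0.05, b=0.051, c=0.0)
        calls = presence_calls(p, 0.05)
        assert calls == {"a": False, "b": True, "c": False}

    def test_empty_profile(self):
        assert presence_calls(profile("P1", 0), 0.05) == {}

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            presence_calls(profile("P1", 0, a=0.5), 0.0)


class TestSequentialNetwork:
    def test_four_alteration_toy(self):
        """A from t1; B, C from t2; D from t3 gives the five pairwise
        earlier-than edges and no B-C edge (tied first appearance)."""
        profiles = [
            profile("P1", 1, A=0.5, B=0.0, C=0.0, D=0.0),
            profile("P1", 2, A=0.5, B=0.4, C=0.3, D=0.0),
            profile("P1", 3, A=0.5, B=0.4, C=0.3, D=0.2),
        ]
        g = build_sequential_network(profiles)
        assert set(g.edges) == {("A", "B"), ("A", "C"), ("A", "D"),
                                ("B", "D"), ("C", "D")}
        assert g.role == "sequential"

    def test_single_present_lesion_no_edges(self):
        g = build_sequential_network([
            profile("P1", 0, A=0.5), profile("P1", 6, A=0.5)])
        assert set(g.nodes) == {"A"} and g.number_of_edges() == 0

    def test_simultaneous_first_presence_gets_no_edge(self):
        g = build_sequential_network([
            profile("P1", 0, A=0.0, B=0.0),
            profile("P1", 6, A=0.5, B=0.5)])
        assert g.number_of_edges() == 0

    def test_never_present_lesion_excluded(self):
        g = build_sequential_network([
            profile("P1", 0, A=0.5, B=0.01),
            profile("P1", 6, A=0.5, B=0.04)])
        assert "B" not in g.nodes

    def test_disappearing_lesion_keeps_first_time(self):
        g = build_sequential_network([
            profile("P1", 0, A=0.5, B=0.0),
            profile("P1", 6, A=0.0, B=0.5),
            profile("P1", 12, A=0.0, B=0.5)])
        assert set(g.edges) == {("A", "B")}

    def test_requires_two_time_points(self):
        with pytest.raises(ValueError, match=">= 2 time points"):
            build_sequential_network([profile("P1", 0, A=0.5)])


def seq_net(pid, edges, nodes=()):
    g = OrderGraph(role="sequential")
    g.graph["patient_id"] = pid
    for n in nodes:
        g.add_node(n, recurrence=1)
    for u, v in edges:
        g.add_node(u, recurrence=1)
        g.add_node(v, recurrence=1)
        g.add_edge(u, v, weight=1, patients=frozenset({pid}))
    return g


class TestPoolIsn:
    def test_shared_edge_counts_patients(self):
        isn = pool_isn([seq_net("P1", [("A", "B")]),
                        seq_net("P2", [("A", "B")])])
        assert isn["A"]["B"]["weight"] == 2
        assert isn["A"]["B"]["patients"] == {"P1", "P2"}
        assert isn.nodes["A"]["recurrence"] == 2

    def test_disjoint_lesions_union(self):
        isn = pool_isn([seq_net("P1", [("A", "B")]),
                        seq_net("P2", [("C", "D")])])
        assert set(isn.edges) == {("A", "B"), ("C", "D")}
        assert all(d["weight"] == 1 for _, _, d in isn.edges(data=True))

    def test_matches_direct_tally_oracle(self):
        """ISN weights equal an independent recount over raw presence
        profiles of 15 simulated patients."""
        from tedg.evosim import EvolutionModel, cohort_profiles, \
            simulate_cohort

        cohort = simulate_cohort(EvolutionModel(kind="linear"), 15, seed=21)
        prof = cohort_profiles(cohort)
        isn = pool_isn([build_sequential_network(p)
                        for p in prof.values()])
        # oracle: tally first-presence comparisons straight from profiles
        tally: dict = {}
        for profiles in prof.values():
            first: dict = {}
            for p in sorted(profiles, key=lambda x: x.sample_time):
                for lesion, mcf in p.mcf.items():
                    if mcf > 0.05 and lesion not in first:
                        first[lesion] = p.sample_time
            for a, b in itertools.permutations(first, 2):
                if first[a] < first[b]:
                    tally[(a, b)] = tally.get((a, b), 0) + 1
        assert {(u, v): d["weight"]
                for u, v, d in isn.edges(data=True)} == tally

    def test_rejects_non_sequential_input(self):
        with pytest.raises(ValueError):
            pool_isn([OrderGraph(role="ISN")])


class TestSimplifyIsn:
    def make_isn(self, edges):
        g = OrderGraph(role="ISN")
        for u, v, w in edges:
            g.add_node(u, recurrence=1)
            g.add_node(v, recurrence=1)
            g.add_edge(u, v, weight=w, patients=frozenset({"p"}))
        return g

    def test_reciprocal_pair_subtracts_weaker(self):
        g = simplify_isn(self.make_isn([("A", "B", 3), ("B", "A", 1)]))
        assert set(g.edges) == {("A", "B")}
        assert g["A"]["B"]["weight"] == 2

    def test_balanced_pair_cancels(self):
        g = simplify_isn(self.make_isn([("A", "B", 2), ("B", "A", 2)]))
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}

    def test_no_reciprocals_is_identity(self):
        edges = [("A", "B", 2), ("B", "C", 3), ("A", "C", 1)]
        g = simplify_isn(self.make_isn(edges))
        assert {(u, v): d["weight"] for u, v, d in g.edges(data=True)} == \
            {(u, v): w for u, v, w in edges}


def graph_from_weights(weights, role="simplified"):
    g = OrderGraph(role=role)
    for (u, v), w in weights.items():
        g.add_node(u, recurrence=1)
        g.add_node(v, recurrence=1)
        g.add_edge(u, v, weight=w)
    return g


class TestDeconvolve:
    def test_beta_to_zero_limit_is_identity(self):
        g = graph_from_weights({("A", "B"): 3, ("B", "C"): 2,
                                ("A", "C"): 4})
        dec = deconvolve(g, beta=1e-8)
        for u, v, d in g.edges(data=True):
            assert dec[u][v]["weight"] == pytest.approx(d["weight"],
                                                        abs=1e-6)

    def test_single_edge_unchanged_for_any_beta(self):
        for beta in (0.1, 0.5, 0.9):
            dec = deconvolve(graph_from_weights({("A", "B"): 7}), beta)
            assert dec["A"]["B"]["weight"] == pytest.approx(7.0)

    def test_three_node_chain_symbolic_expansion(self):
        """Chain A->B->C plus shortcut A->C at weight 1: the nilpotent
        series gives A->C = 1 - beta, direct edges unchanged."""
        g = graph_from_weights({("A", "B"): 1, ("B", "C"): 1,
                                ("A", "C"): 1})
        dec = deconvolve(g, beta=0.2)
        assert dec["A"]["C"]["weight"] == pytest.approx(0.8)
        assert dec["A"]["B"]["weight"] == pytest.approx(1.0)
        assert dec["B"]["C"]["weight"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_inverts_forward_series_on_random_dags(self, seed):
        """deconvolve exactly inverts G_obs = G_dir (I - beta G_dir)^-1
        when beta * spectral_radius < 1."""
        rng = np.random.default_rng(seed)
        n, beta = 6, 0.2
        nodes = [f"v{i}" for i in range(n)]
        g_dir = np.triu(rng.uniform(0.2, 2.0, (n, n)), k=1)
        g_dir *= rng.random((n, n)) < 0.5
        g_obs = g_dir @ np.linalg.inv(np.eye(n) - beta * g_dir)
        g = OrderGraph(role="simplified")
        g.add_nodes_from(nodes)
        for i, j in itertools.product(range(n), range(n)):
            if g_obs[i, j] > 1e-12:
                g.add_edge(nodes[i], nodes[j], weight=g_obs[i, j])
        dec = deconvolve(g, beta)
        for i, j in itertools.product(range(n), range(n)):
            got = dec[nodes[i]][nodes[j]]["weight"] \
                if dec.has_edge(nodes[i], nodes[j]) else 0.0
            assert got == pytest.approx(g_dir[i, j], abs=1e-8)

    def test_permutation_invariance(self):
        weights = {("b", "a"): 2.0, ("b", "c"): 3.0, ("a", "c"): 1.5}
        renamed = {(u.upper(), v.upper()): w for (u, v), w in
                   weights.items()}
        d1 = deconvolve(graph_from_weights(weights), 0.3)
        d2 = deconvolve(graph_from_weights(renamed), 0.3)
        for (u, v), _ in weights.items():
            w1 = d1[u][v]["weight"] if d1.has_edge(u, v) else None
            w2 = d2[u.upper()][v.upper()]["weight"] \
                if d2.has_edge(u.upper(), v.upper()) else None
            assert w1 == pytest.approx(w2)

    def test_singular_matrix_advises_smaller_beta(self):
        # 4-cycle with weight 5 has eigenvalue -5; beta = 0.2 hits -1
        g = graph_from_weights({("A", "B"): 5, ("B", "C"): 5,
                                ("C", "D"): 5, ("D", "A"): 5})
        with pytest.raises(np.linalg.LinAlgError, match="smaller beta"):
            deconvolve(g, 0.2)


def spanning_tree_oracle(weights):
    """Enumerate all undirected spanning trees, return the min-cost sets."""
    und = {}
    for (u, v), w in weights.items():
        key = frozenset((u, v))
        und[key] = min(und.get(key, np.inf), math.exp(-w))
    nodes = sorted({x for e in weights for x in e})
    n = len(nodes)
    best_cost, best = np.inf, []
    for combo in itertools.combinations(und, n - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(tuple(e) for e in combo)
        if not nx.is_connected(g):
            continue
        cost = sum(und[e] for e in combo)
        if cost < best_cost - 1e-15:
            best_cost, best = cost, [set(combo)]
        elif abs(cost - best_cost) <= 1e-15:
            best.append(set(combo))
    return best_cost, best


class TestExtractTedg:
    CHAIN = {("A", "B"): 1.0, ("B", "C"): 1.0, ("C", "D"): 1.0,
             ("A", "C"): 0.8, ("A", "D"): 0.6}

    def test_chain_recovered_against_enumeration(self):
        tree = extract_tedg(graph_from_weights(self.CHAIN, "deconvolved"))
        assert set(tree.edges) == {("A", "B"), ("B", "C"), ("C", "D")}
        _, best = spanning_tree_oracle(self.CHAIN)
        assert {frozenset(e) for e in tree.edges} in best

    @pytest.mark.parametrize("seed", range(5))
    def test_minimality_by_exhaustive_enumeration(self, seed):
        """Tree cost is no larger than any other spanning tree's for
        random weighted DAGs with n <= 6."""
        rng = np.random.default_rng(seed)
        nodes = list("ABCDEF")[:int(rng.integers(4, 7))]
        weights = {}
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if rng.random() < 0.7:
                    weights[(u, v)] = float(rng.uniform(0.2, 4.0))
        g = graph_from_weights(weights, "deconvolved")
        if not nx.is_weakly_connected(g):
            return
        tree = extract_tedg(g)
        cost = sum(math.exp(-d["weight"])
                   for _, _, d in tree.edges(data=True))
        best_cost, _ = spanning_tree_oracle(weights)
        assert cost <= best_cost + 1e-12

    def test_tree_has_n_minus_1_edges_and_acyclic(self):
        g = graph_from_weights(self.CHAIN, "deconvolved")
        tree = extract_tedg(g)
        assert tree.number_of_edges() == tree.number_of_nodes() - 1
        assert nx.is_directed_acyclic_graph(tree)

    def test_empty_graph_gives_empty_tree(self):
        g = OrderGraph(role="deconvolved")
        g.add_node("A", recurrence=1)
        tree = extract_tedg(g)
        assert tree.number_of_edges() == 0

    def test_arborescence_recovers_chain(self):
        tree = extract_tedg(graph_from_weights(self.CHAIN, "deconvolved"),
                            method="arborescence")
        assert set(tree.edges) == {("A", "B"), ("B", "C"), ("C", "D")}

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            extract_tedg(OrderGraph(role="deconvolved"), method="kruskal")


class TestTedgConfig:
    def test_defaults(self):
        cfg = TedgConfig()
        assert cfg.beta == 0.2 and cfg.presence_threshold == 0.05

    @pytest.mark.parametrize("kwargs", [
        {"beta": 0.0}, {"beta": 1.0}, {"presence_threshold": 0.0},
        {"tree_method": "kruskal"},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            TedgConfig(**kwargs)
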
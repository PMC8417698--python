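import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprio import crosstalk as ct
from netprio.exceptions import ConfigurationError
from netprio.genesets import GeneSetCollection
from tests.conftest import toy_priority


def exhaustive_best_score(graph, scores):
    """Independent oracle: max score over ALL connected induced subgraphs."""
    nodes = sorted(graph.nodes)
    best = -np.inf
    for size in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            if nx.is_connected(graph.subgraph(subset)):
                best = max(best, sum(scores[g] for g in subset))
    return best


def random_instance(seed, n_max=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    graph = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: f"n{i:02d}" for i in graph.nodes})
    scores = {g: float(rng.normal(0, 1)) for g in graph.nodes}
    if not any(s > 0 for s in scores.values()):
        scores[sorted(scores)[0]] = 1.0
    return graph, scores


class TestScoreNodes:
    def test_theta_zero_all_non_negative(self, small_priority):
        assert (ct.score_nodes(small_priority, 0.0) >= 0).all()

    def test_theta_five_all_non_positive(self, small_priority):
        assert (ct.score_nodes(small_priority, 5.0) <= 0).all()

    def test_median_theta_splits_half(self):
        priority = toy_priority({f"g{i}": i / 2.0 for i in range(1, 11)})
        theta = float(np.median(priority["rating"]))
        scores = ct.score_nodes(priority, theta)
        assert (scores > 0).sum() == 5

    def test_theta_out_of_range(self, small_priority):
        with pytest.raises(ValueError):
            ct.score_nodes(small_priority, 6.0)


class TestFindCrosstalk:
    def test_all_positive_connected_returns_whole_graph(self):
        g = nx.relabel_nodes(nx.cycle_graph(6), str)
        scores = {n: 1.0 for n in g.nodes}
        module = ct.find_crosstalk(g, scores)
        assert set(module.genes) == set(g.nodes)

    def test_bridge_node_included_when_worth_it(self):
        # two positive triangles joined by one mildly negative bridge;
        # decoys strongly negative
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3")])
        g.add_edges_from([("b1", "b2"), ("b2", "b3"), ("b1", "b3")])
        g.add_edges_from([("a1", "bridge"), ("bridge", "b1")])
        g.add_edges_from([("a2", "x1"), ("b2", "x2"), ("x1", "x3"), ("x2", "x4"), ("x3", "x5")])
        scores = {n: 1.0 for n in ["a1", "a2", "a3", "b1", "b2", "b3"]}
        scores["bridge"] = -0.5
        scores.update({f"x{i}": -2.0 for i in range(1, 6)})
        module = ct.find_crosstalk(g, scores)
        assert "bridge" in module.genes
        assert module.total_score == pytest.approx(5.5)
        assert module.total_score == pytest.approx(exhaustive_best_score(g, scores))

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_mode_matches_oracle(self, seed):
        graph, scores = random_instance(seed)
        module = ct.find_crosstalk(graph, scores)
        assert module.total_score == pytest.approx(exhaustive_best_score(graph, scores))

    @pytest.mark.parametrize("seed", range(15))
    def test_heuristic_mode_near_optimal_and_connected(self, seed):
        graph, scores = random_instance(seed)
        params = ct.CrosstalkParams(exact_max_nodes=0)  # force heuristic path
        module = ct.find_crosstalk(graph, scores, params)
        assert nx.is_connected(graph.subgraph(module.genes))
        opt = exhaustive_best_score(graph, scores)
        assert module.total_score <= opt + 1e-9
        assert module.total_score >= max(s for s in scores.values()) - 1e-9
        assert module.total_score >= 0.75 * opt - 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_module_connected_on_larger_graphs(self, seed):
        rng = np.random.default_rng(seed + 100)
        graph = nx.relabel_nodes(
            nx.barabasi_albert_graph(60, 2, seed=seed), lambda i: f"n{i:02d}"
        )
        scores = {g: float(rng.normal(-0.5, 1)) for g in graph.nodes}
        if not any(s > 0 for s in scores.values()):
            scores[sorted(scores)[0]] = 1.0
        module = ct.find_crosstalk(graph, scores)
        assert nx.is_connected(graph.subgraph(module.genes))
        assert module.total_score >= max(scores.values()) - 1e-9

    def test_no_positive_score_errors(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="no signal"):
            ct.find_crosstalk(g, {"a": -1.0, "b": 0.0})

    def test_params_validation(self):
        with pytest.raises(ConfigurationError):
            ct.CrosstalkParams(n_perm=5)


class TestPermutation:
    def test_constant_scores_give_p_one(self):
        g = nx.relabel_nodes(nx.cycle_graph(8), str)
        scores = {n: 1.0 for n in g.nodes}
        module = ct.find_crosstalk(g, scores)
        res = ct.permutation_significance(
            g, scores, module.total_score, ct.CrosstalkParams(n_perm=20, seed=1)
        )
        assert res.p_empirical == pytest.approx(1.0)

    def test_empirical_floor_is_pseudocount(self):
        # smallest achievable empirical p with 100 permutations
        assert 1 / (1 + 100) == pytest.approx(0.0099, abs=1e-4)

    @pytest.mark.parametrize("width", [1, 2])
    def test_degree_bins_preserve_score_multisets(self, width):
        rng = np.random.default_rng(3)
        graph = nx.relabel_nodes(
            nx.barabasi_albert_graph(40, 2, seed=3), lambda i: f"n{i:02d}"
        )
        scores = {g: float(rng.normal(0, 1)) for g in graph.nodes}
        for _ in range(50):
            shuffled = ct.permute_scores_within_degree_bins(graph, scores, rng, width)
            bins = {}
            for g in graph.nodes:
                bins.setdefault(graph.degree(g) // width, ([], []))
                bins[graph.degree(g) // width][0].append(round(scores[g], 9))
                bins[graph.degree(g) // width][1].append(round(shuffled[g], 9))
            for orig, new in bins.values():
                assert Counter(orig) == Counter(new)

    def test_extrapolated_p_reported(self):
        rng = np.random.default_rng(9)
        graph = nx.relabel_nodes(
            nx.barabasi_albert_graph(30, 2, seed=9), lambda i: f"n{i:02d}"
        )
        scores = {g: float(rng.normal(0, 1)) for g in graph.nodes}
        module = ct.find_crosstalk(graph, scores)
        res = ct.permutation_significance(
            graph, scores, module.total_score, ct.CrosstalkParams(n_perm=30, seed=2)
        )
        assert 0 <= res.p_extrapolated <= 1
        assert res.p_empirical >= 1 / 31


def disjoint_collection(shared_counts, fill=4):
    """Build pathway sets with exactly the requested pairwise shared counts."""
    ids = sorted({p for pair in shared_counts for p in pair})
    members = {p: set() for p in ids}
    serial = 0
    for (p1, p2), count in shared_counts.items():
        for _ in range(count):
            gene = f"sh{serial:03d}"
            serial += 1
            members[p1].add(gene)
            members[p2].add(gene)
    for p in ids:
        for _ in range(fill):
            members[p].add(f"u{serial:03d}")
            serial += 1
    return GeneSetCollection([(p, p, members[p]) for p in ids])


class TestPathwayGraph:
    def test_triangle_equal_sharing_keeps_two_edges(self):
        sets = disjoint_collection({("A", "B"): 2, ("B", "C"): 2, ("A", "C"): 2})
        universe = sets.universe()
        pg = ct.pathway_graph(universe, sets, universe, fdr_threshold=2.0)
        assert len(pg.edges) == 3
        assert pg.edges["mst_flag"].sum() == 2

    def test_hand_kruskal(self):
        sets = disjoint_collection({("A", "B"): 6, ("B", "C"): 6, ("A", "C"): 1})
        universe = sets.universe()
        pg = ct.pathway_graph(universe, sets, universe, fdr_threshold=2.0)
        kept = {
            tuple(sorted((r["p1"], r["p2"])))
            for _, r in pg.edges.iterrows()
            if r["mst_flag"]
        }
        assert kept == {("A", "B"), ("B", "C")}

    def test_single_pathway_warns(self):
        sets = GeneSetCollection([("A", "A", {"g1", "g2"})])
        with pytest.warns(UserWarning, match="significant"):
            pg = ct.pathway_graph({"g1", "g2"}, sets, {"g1", "g2", "g3"}, 2.0)
        assert len(pg.edges) == 0

    def test_only_significant_pathways_are_nodes(self, small_dataset, small_priority):
        from netprio import prioritize as pz

        module_genes = set(pz.top_fraction(small_priority, 0.05))
        pg = ct.pathway_graph(
            module_genes, small_dataset.genesets, set(small_priority["gene"]), 0.05
        )
        assert (pg.nodes["FDR"] < 0.05).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_mst_matches_bruteforce_spanning_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        ids = [chr(65 + i) for i in range(n)]
        shared = {}
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.7:
                shared[(ids[i], ids[j])] = int(rng.integers(1, 9))
        graph = nx.Graph(list(shared))
        if graph.number_of_nodes() < 3 or not nx.is_connected(graph):
            pytest.skip("instance not connected")
        sets = disjoint_collection(shared)
        universe = sets.universe()
        pg = ct.pathway_graph(universe, sets, universe, fdr_threshold=2.0)
        mst_dist = sum(
            1.0 / r["shared_count"] for _, r in pg.edges.iterrows() if r["mst_flag"]
        )
        # brute force over all spanning trees
        edges = list(shared)
        best = np.inf
        for subset in itertools.combinations(edges, graph.number_of_nodes() - 1):
            t = nx.Graph(subset)
            if t.number_of_nodes() == graph.number_of_nodes() and nx.is_tree(t):
                best = min(best, sum(1.0 / shared[e] for e in subset))
        assert mst_dist == pytest.approx(best)
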
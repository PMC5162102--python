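"""De novo gene-set detection: graph, weights, clustering, permutation test."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from mecotest import (
    AlterationMatrix,
    MEGraph,
    build_me_graph,
    cluster_me_graph,
    edge_overlap_permutation_test,
    estimate_binomial_background,
    weight_edges,
)
from mecotest.denovo import _atom_similarity, _atoms, _objective, validate_groups
from mecotest.independence import PairResult, test_group as run_group_test
from mecotest.independence import test_pair as run_pair_test


def pair(a, b, q, direction="exclusivity"):
    return PairResult(gene_a=a, gene_b=b, direction=direction,
                      observed_overlap=0, expected_overlap=1.0,
                      p_value=q / 2, support_size=10, q_value=q)


class TestBuildGraph:
    def test_no_significant_pairs_gives_empty_graph(self):
        g = build_me_graph([pair("A", "B", 0.5)], max_fdr=0.10)
        assert g.n_edges == 0 and g.nodes == []

    def test_threshold_is_inclusive_filter(self):
        g = build_me_graph(
            [pair("A", "B", 0.05), pair("A", "C", 0.15)], max_fdr=0.10
        )
        assert g.n_edges == 1
        assert g.graph.has_edge("A", "B")

    def test_edge_count_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(12)]
        results = [
            pair(a, b, float(rng.uniform(0, 0.4)))
            for a, b in combinations(genes, 2)
        ]
        g = build_me_graph(results, max_fdr=0.10)
        assert g.n_edges == sum(r.q_value <= 0.10 for r in results)

    def test_missing_q_value_is_an_error(self):
        r = pair("A", "B", 0.01)
        r.q_value = None
        with pytest.raises(ValueError, match="no q-value"):
            build_me_graph([r])

    def test_cooccurrence_results_ignored(self):
        g = build_me_graph([pair("A", "B", 0.01, direction="cooccurrence")])
        assert g.n_edges == 0


def two_cliques_graph(q=0.001):
    results = []
    for clique in (["a1", "a2", "a3"], ["b1", "b2", "b3"]):
        for u, v in combinations(clique, 2):
            results.append(pair(u, v, q))
    return build_me_graph(results, max_fdr=0.10)


class TestWeightEdges:
    def test_disjoint_cliques_weighted_equally(self):
        g = weight_edges(two_cliques_graph())
        weights = {d["weight"] for _, _, d in g.graph.edges(data=True)}
        assert len(weights) == 1

    def test_star_center_edges_below_clique_edges(self):
        results = [pair("hub", f"s{i}", 0.001) for i in range(5)]
        for u, v in combinations(["c1", "c2", "c3"], 2):
            results.append(pair(u, v, 0.001))
        g = weight_edges(build_me_graph(results))
        star_w = [g.graph["hub"][f"s{i}"]["weight"] for i in range(5)]
        clique_w = [g.graph[u][v]["weight"]
                    for u, v in combinations(["c1", "c2", "c3"], 2)]
        assert max(star_w) < min(clique_w)

    def test_weights_invariant_under_relabeling(self):
        g1 = weight_edges(two_cliques_graph())
        mapping = {n: f"X_{n}" for n in g1.graph.nodes}
        g2raw = two_cliques_graph()
        g2 = MEGraph(nx.relabel_nodes(g2raw.graph, mapping), [])
        g2 = weight_edges(g2)
        for u, v, d in g1.graph.edges(data=True):
            assert g2.graph[mapping[u]][mapping[v]]["weight"] == d["weight"]

    def test_weaker_evidence_gets_lower_weight(self):
        strong = weight_edges(build_me_graph([pair("A", "B", 1e-6)]))
        weak = weight_edges(build_me_graph([pair("A", "B", 0.09)]))
        assert (weak.graph["A"]["B"]["weight"]
                < strong.graph["A"]["B"]["weight"])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            weight_edges(MEGraph(nx.Graph(), []))


def exhaustive_partition_objective(g: MEGraph, nonedge_penalty=0.5):
    """Oracle: best single-membership partition by exhaustive enumeration."""
    atoms = _atoms(g)
    S = _atom_similarity(g, atoms, nonedge_penalty)
    k = len(atoms)
    assert k <= 8, "oracle only tractable for small graphs"

    best = -np.inf
    best_labels = None

    def grow(labels, nxt):
        nonlocal best, best_labels
        if nxt == k:
            obj = _objective(S, [{c} for c in labels])
            if obj > best:
                best, best_labels = obj, list(labels)
            return
        for c in range(max(labels, default=-1) + 2):
            grow(labels + [c], nxt + 1)

    grow([], 0)
    clusters = {}
    for a, c in enumerate(best_labels):
        clusters.setdefault(c, set()).update(atoms[a])
    return best, [frozenset(c) for c in clusters.values() if len(c) >= 2]


class TestClustering:
    def test_two_disjoint_cliques_recovered_and_optimal(self):
        g = weight_edges(two_cliques_graph())
        candidates = cluster_me_graph(g, seed=0)
        found = {frozenset(c.genes) for c in candidates}
        assert found == {frozenset(["a1", "a2", "a3"]),
                         frozenset(["b1", "b2", "b3"])}
        # local search reaches the exhaustive-search optimum
        best_obj, best_sets = exhaustive_partition_objective(g)
        assert set(best_sets) == found

    def test_single_edge_gives_one_pair_candidate(self):
        g = weight_edges(build_me_graph([pair("A", "B", 0.01)]))
        candidates = cluster_me_graph(g, seed=0)
        assert [sorted(c.genes) for c in candidates] == [["A", "B"]]

    def test_must_link_atoms_never_separated(self):
        raw = two_cliques_graph()
        g = weight_edges(MEGraph(raw.graph, [frozenset({"a1", "b1"})]))
        candidates = cluster_me_graph(g, seed=0)
        for c in candidates:
            members = set(c.genes)
            assert ("a1" in members) == ("b1" in members)

    def test_empty_graph_gives_no_candidates(self):
        assert cluster_me_graph(MEGraph(nx.Graph(), []), seed=0) == []

    def test_deterministic_given_seed(self):
        g = weight_edges(two_cliques_graph())
        c1 = cluster_me_graph(g, seed=3)
        c2 = cluster_me_graph(g, seed=3)
        assert [c.genes for c in c1] == [c.genes for c in c2]


class TestValidateGroups:
    @staticmethod
    def _exclusive_matrix():
        # genes a, b, c partition 30 tumors; d, e are random fillers
        rng = np.random.default_rng(0)
        v = np.zeros((5, 30), dtype=int)
        v[0, :10] = v[1, 10:20] = v[2, 20:30] = 1
        v[3] = rng.uniform(size=30) < 0.4
        v[4] = rng.uniform(size=30) < 0.4
        return AlterationMatrix(v, list("abcde"), [f"t{j}" for j in range(30)])

    def test_two_gene_candidate_equals_pairwise_result(self):
        from mecotest import GeneSet

        X = self._exclusive_matrix()
        P = estimate_binomial_background(X)
        res = validate_groups([GeneSet("s", "", ["a", "b"])], X, P, max_fdr=1.0)
        assert len(res) == 1
        expected = run_pair_test(X, P, "a", "b", "exclusivity")
        assert res[0].p_value == pytest.approx(expected.p_value, abs=1e-12)

    def test_exclusive_triple_validates_random_pair_does_not(self):
        from mecotest import GeneSet

        X = self._exclusive_matrix()
        P = estimate_binomial_background(X)
        kept = validate_groups(
            [GeneSet("planted", "", ["a", "b", "c"]),
             GeneSet("noise", "", ["d", "e"])],
            X, P, max_fdr=0.01,
        )
        assert [r.genes.name for r in kept] == ["planted"]


class TestEdgeOverlapPermutation:
    @staticmethod
    def _graph(edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return g

    def test_identical_graphs_give_full_overlap_and_tiny_p(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "e"), ("e", "f"),
                 ("g", "h")]
        g = self._graph(edges)
        g.add_nodes_from(f"z{i}" for i in range(10))  # widen label universe
        overlap, expected, p = edge_overlap_permutation_test(g, g, n_perm=199,
                                                             seed=0)
        assert overlap == len(edges)
        assert expected < overlap
        assert p == pytest.approx(1 / 200)

    def test_edge_disjoint_graphs_over_many_labels(self):
        nodes = [f"n{i}" for i in range(30)]
        gA = self._graph([(nodes[i], nodes[i + 1]) for i in range(0, 10, 2)])
        gB = self._graph([(nodes[i], nodes[i + 1]) for i in range(20, 28, 2)])
        overlap, expected, p = edge_overlap_permutation_test(gA, gB, n_perm=199,
                                                            seed=1)
        assert overlap == 0
        assert p > 0.5

    def test_half_shared_random_graphs_significant(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(40)]
        shared = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(15)]
        onlyA = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(15)]
        onlyB = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(15)]
        gA = self._graph(shared + onlyA)
        gB = self._graph(shared + onlyB)
        _, expected, p = edge_overlap_permutation_test(gA, gB, n_perm=999, seed=2)
        assert p < 0.01
        assert expected < len(shared)

    def test_zero_permutations_rejected(self):
        g = self._graph([("a", "b")])
        with pytest.raises(ValueError, match="n_perm"):
            edge_overlap_permutation_test(g, g, n_perm=0)
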
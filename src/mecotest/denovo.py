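"""De novo detection of mutually exclusive gene sets.

Starting from pairwise mutual exclusivity results, candidate gene sets
are found in three steps:

1. **Graph construction** — genes become nodes, and an edge connects two
   genes whose pairwise exclusivity passes a permissive FDR threshold
   (10% by default), so borderline pairs are not lost before grouping.

2. **Edge weighting and clustering** — a gene that is exclusive with many
   unrelated genes produces edges that say little about set membership,
   so each edge is down-weighted by the degree-based expected edge count,
   ``w_uv = 1 - d_u * d_v / (2 |E|)`` (clipped below at a floor): edges
   between low-degree genes weigh more than edges spanning hubs.  Gene
   sets are then extracted by overlapping correlation clustering — a
   seeded local search that maximizes within-cluster similarity, allows a
   gene to join more than one cluster, and honors must-link constraints
   (e.g. genes in one copy-number segment, or the mutation and
   copy-number events of the same gene, always travel together).

3. **Validation** — every candidate set is tested with the groupwise
   impurity test under discrete FDR control at a strict threshold (1% by
   default); only validated sets are reported.

A generic label-shuffling permutation test for the edge overlap between
two gene graphs (e.g. the exclusivity graph versus a functional
interaction network) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .alteration_data import AlterationMatrix, GeneSet
from .background import BackgroundMatrix
from .fdr import attainable_pvalues, discrete_fdr
from .independence import GroupResult, PairResult, test_group
from .poibin import PoissonBinomial

__all__ = [
    "MEGraph",
    "build_me_graph",
    "weight_edges",
    "cluster_me_graph",
    "validate_groups",
    "edge_overlap_permutation_test",
]

ALGORITHM_TAG = "overlapping-correlation-clustering-local-search/0.1"


@dataclass
class MEGraph:
    """Weighted mutual exclusivity graph with optional must-link groups."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    must_link: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(u, u) for u in self.graph):
            raise ValueError("self-edges are not allowed")
        seen: set[str] = set()
        for grp in self.must_link:
            if seen & grp:
                raise ValueError("must-link groups must be disjoint")
            missing = grp - set(self.graph.nodes)
            if missing:
                raise ValueError(f"must-link members not in graph: {sorted(missing)}")
            seen |= grp

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_me_graph(
    results: Iterable[PairResult],
    max_fdr: float = 0.10,
    must_link: Sequence[Iterable[str]] = (),
) -> MEGraph:
    """Connect genes whose pairwise exclusivity has q-value <= ``max_fdr``.

    Only exclusivity-direction results with q-values are considered;
    nodes are the genes incident to at least one retained edge.
    Must-link groups are filtered to their members present in the graph.
    """
    g = nx.Graph()
    for r in results:
        if r.direction != "exclusivity":
            continue
        if r.q_value is None:
            raise ValueError(
                f"pair ({r.gene_a}, {r.gene_b}) carries no q-value; run FDR first"
            )
        if r.q_value <= max_fdr:
            g.add_edge(r.gene_a, r.gene_b, weight=1.0, q_value=r.q_value)
    nodes = set(g.nodes)
    ml = [frozenset(grp) & nodes for grp in (frozenset(m) for m in must_link)]
    ml = [m for m in ml if len(m) >= 2]
    return MEGraph(g, ml)


def weight_edges(
    g: MEGraph, floor: float = 0.01, significance_scale: float = 3.0
) -> MEGraph:
    """Down-weight hub-spanning edges by their degree-based expectation.

    Each edge (u, v) gets weight ``s_uv * (1 - sqrt(d_u * d_v) / (2
    |E|))``, clipped below at ``floor``.  The degree factor discounts
    edges by how expected they are under random graphs with the same
    degree sequence, so edges of promiscuously exclusive genes count less
    towards cluster membership than specific edges between low-degree
    nodes; the geometric mean keeps the correction in scale when node
    degrees are large relative to the edge count (a raw degree product
    can exceed ``2 |E|``, which would zero out exactly the edges inside
    densely connected groups).  The factor ``s_uv = min(1, -log10(q_uv) /
    significance_scale)`` scales each edge by the strength of its
    exclusivity evidence, so that barely-significant edges (q near the
    graph threshold) cannot outrank firmly established edges inside a
    dense group.  Edges without a stored q-value get ``s_uv = 1``.
    """
    if g.n_edges < 1:
        raise ValueError("graph has no edges to weight")
    out = g.graph.copy()
    two_e = 2.0 * g.n_edges
    for u, v in out.edges:
        w = 1.0 - np.sqrt(out.degree[u] * out.degree[v]) / two_e
        q = out[u][v].get("q_value")
        if q is not None and significance_scale > 0:
            strength = min(1.0, -np.log10(max(float(q), 1e-12)) / significance_scale)
            w *= max(strength, 0.0)
        out[u][v]["weight"] = max(w, floor)
    return MEGraph(out, list(g.must_link))


# -- overlapping correlation clustering ------------------------------------


def _atoms(g: MEGraph) -> list[tuple[str, ...]]:
    """Nodes grouped into must-link atoms (singletons otherwise)."""
    in_ml = {n for grp in g.must_link for n in grp}
    atoms = [tuple(sorted(grp)) for grp in g.must_link]
    atoms += [(n,) for n in g.nodes if n not in in_ml]
    return sorted(atoms)


def _atom_similarity(g: MEGraph, atoms: list[tuple[str, ...]], nonedge_penalty: float) -> np.ndarray:
    """Summed node-pair similarity between atoms: edge weight for edges,
    ``-nonedge_penalty`` for absent edges."""
    k = len(atoms)
    S = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            s = 0.0
            for u in atoms[a]:
                for v in atoms[b]:
                    if g.graph.has_edge(u, v):
                        s += g.graph[u][v]["weight"]
                    else:
                        s -= nonedge_penalty
            S[a, b] = S[b, a] = s
    return S


def _objective(S: np.ndarray, assign: list[set[int]]) -> float:
    """Jaccard-weighted agreement: each atom pair contributes its summed
    similarity scaled by the Jaccard overlap of the two label sets.

    The Jaccard scaling is what keeps overlapping assignments honest: an
    atom that joins extra clusters to collect edge weight dilutes the
    overlap on each of its edges, so splitting a dense group into
    overlapping fragments scores below keeping it in one cluster."""
    total = 0.0
    k = len(assign)
    for a in range(k):
        sa = assign[a]
        for b in range(a + 1, k):
            inter = len(sa & assign[b])
            if inter:
                total += S[a, b] * inter / len(sa | assign[b])
    return total


def cluster_me_graph(
    g: MEGraph,
    max_clusters: int | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    nonedge_penalty: float = 0.5,
    max_memberships: int = 2,
) -> list[GeneSet]:
    """Extract candidate gene sets by overlapping correlation clustering.

    Seeded local search over cluster assignments of must-link atoms:
    moves reassign an atom to any single cluster (existing or new) or add
    a secondary membership (up to ``max_memberships``), accepted only
    when the within-cluster similarity objective improves, so the
    objective is non-decreasing across iterations.  The best of
    ``n_restarts`` randomized restarts is returned.  Atoms move as units,
    so must-link constraints hold in every emitted candidate.  Clusters
    with at least two nodes become :class:`GeneSet` candidates.
    """
    if g.n_edges == 0:
        return []
    atoms = _atoms(g)
    k = len(atoms)
    if max_clusters is None:
        max_clusters = k  # every atom may stand alone
    S = _atom_similarity(g, atoms, nonedge_penalty)
    rng = np.random.default_rng(seed)

    best_assign: list[set[int]] | None = None
    best_obj = -np.inf
    for restart in range(n_restarts):
        # init: each atom in its own cluster (capped), extras joined randomly
        assign = [{min(i, max_clusters - 1)} for i in range(k)]
        if restart > 0:
            assign = [
                {int(rng.integers(min(k, max_clusters)))} for _ in range(k)
            ]
        improved = True
        guard = 0
        while improved and guard < 200:
            improved = False
            guard += 1
            # single-atom reassignment moves
            order = rng.permutation(k)
            for a in order:
                current = assign[a]
                cur_obj = _objective(S, assign)
                cluster_ids = sorted({c for s in assign for c in s})
                candidates: list[set[int]] = []
                for c in cluster_ids:
                    candidates.append({c})
                    if len(current) < max_memberships and c not in current:
                        candidates.append(current | {c})
                if len(cluster_ids) < max_clusters:
                    fresh = max(cluster_ids, default=-1) + 1
                    candidates.append({fresh})
                best_local, best_local_obj = current, cur_obj
                for cand in candidates:
                    if cand == current:
                        continue
                    assign[a] = cand
                    o = _objective(S, assign)
                    if o > best_local_obj + 1e-12:
                        best_local, best_local_obj = cand, o
                assign[a] = best_local
                if best_local != current:
                    improved = True
            # cluster-merge moves: single-atom moves cannot reunite a dense
            # group once it fragments, so try fusing whole clusters
            merged = True
            while merged:
                merged = False
                cluster_ids = sorted({c for s in assign for c in s})
                cur_obj = _objective(S, assign)
                best_pair, best_obj_m = None, cur_obj
                for ci in range(len(cluster_ids)):
                    for cj in range(ci + 1, len(cluster_ids)):
                        c1, c2 = cluster_ids[ci], cluster_ids[cj]
                        trial = [
                            ({c1} | s - {c2}) if c2 in s else set(s) for s in assign
                        ]
                        o = _objective(S, trial)
                        if o > best_obj_m + 1e-12:
                            best_pair, best_obj_m = (c1, c2), o
                if best_pair is not None:
                    c1, c2 = best_pair
                    assign = [
                        ({c1} | s - {c2}) if c2 in s else set(s) for s in assign
                    ]
                    merged = True
                    improved = True
        obj = _objective(S, assign)
        if obj > best_obj:
            best_obj, best_assign = obj, [set(s) for s in assign]

    assert best_assign is not None
    clusters: dict[int, set[str]] = {}
    for a, memberships in enumerate(best_assign):
        for c in memberships:
            clusters.setdefault(c, set()).update(atoms[a])
    out = []
    for idx, members in enumerate(sorted(clusters.values(), key=sorted)):
        if len(members) >= 2:
            out.append(
                GeneSet(
                    name=f"candidate_{idx:03d}",
                    description=ALGORITHM_TAG,
                    genes=sorted(members),
                )
            )
    return out


def validate_groups(
    candidates: Sequence[GeneSet],
    X: AlterationMatrix,
    P: BackgroundMatrix,
    max_fdr: float = 0.01,
) -> list[GroupResult]:
    """Groupwise impurity test per candidate, under discrete FDR control.

    Returns the candidates whose q-value is at most ``max_fdr`` (1% by
    default), with q-values filled in.
    """
    if not candidates:
        raise ValueError("no candidate gene sets to validate")
    results = [test_group(X, P, c, statistic="impurity") for c in candidates]
    supports = [
        attainable_pvalues(PoissonBinomial(r.event_probs), "lower") for r in results
    ]
    qvals = discrete_fdr([r.p_value for r in results], supports)
    kept = []
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        if q <= max_fdr:
            kept.append(r)
    return kept


def detect_exclusive_sets(
    X: AlterationMatrix,
    P: BackgroundMatrix,
    genes: Sequence[str] | None = None,
    graph_fdr: float = 0.10,
    validate_fdr: float = 0.01,
    must_link: Sequence[Iterable[str]] = (),
    seed: int = 0,
) -> tuple[list[GroupResult], list[GeneSet]]:
    """Full de novo pipeline: pairwise tests, graph, clustering, validation.

    Runs the pairwise exclusivity test over ``genes`` (default: all genes
    of ``X``), applies discrete FDR, builds the exclusivity graph at the
    permissive ``graph_fdr``, clusters it, and validates candidates with
    the groupwise impurity test at the strict ``validate_fdr``.  Returns
    ``(validated group results, all candidate sets)``.
    """
    from .independence import test_all_pairs

    results = test_all_pairs(X, P, "exclusivity", genes=genes)
    supports = [
        attainable_pvalues(PoissonBinomial(r.joint_probs), "lower") for r in results
    ]
    qvals = discrete_fdr([r.p_value for r in results], supports)
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    graph = build_me_graph(results, max_fdr=graph_fdr, must_link=must_link)
    if graph.n_edges == 0:
        return [], []
    candidates = cluster_me_graph(weight_edges(graph), seed=seed)
    if not candidates:
        return [], []
    validated = validate_groups(candidates, X, P, max_fdr=validate_fdr)
    return validated, candidates


def edge_overlap_permutation_test(
    gA: nx.Graph,
    gB: nx.Graph,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Label-shuffling test of the edge overlap between two gene graphs.

    The observed overlap is the number of edges present in both graphs.
    The null distribution is obtained by shuffling the gene labels of
    ``gA`` across the union label universe ``n_perm`` times and re-counting
    the overlap with the unshuffled ``gB``.  Returns ``(overlap, expected,
    p_value)`` with the add-one permutation p-value
    ``(1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    universe = sorted(set(gA.nodes) | set(gB.nodes))
    edges_b = {frozenset(e) for e in gB.edges}
    edges_a = [tuple(e) for e in gA.edges]
    observed = sum(1 for e in edges_a if frozenset(e) in edges_b)

    count_ge = 0
    total = 0.0
    labels = np.asarray(universe, dtype=object)
    index = {lab: i for i, lab in enumerate(universe)}
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        ov = sum(
            1
            for u, v in edges_a
            if frozenset((perm[index[u]], perm[index[v]])) in edges_b
        )
        total += ov
        if ov >= observed:
            count_ge += 1
    expected = total / n_perm
    p = (1 + count_ge) / (n_perm + 1)
    return observed, float(expected), float(p)
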
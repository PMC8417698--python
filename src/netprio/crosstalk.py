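"""Maximum-scoring connected subnetwork discovery with a degree-preserving null.

Node scores are shifted ratings (rating - theta). The search returns a
connected subgraph maximizing the score sum: exact enumeration on small
graphs, and a Steiner-style heuristic on larger ones (positive components
joined by cheapest negative-penalty paths, followed by an exact best-subtree
extraction on a spanning tree of the candidate region). Significance comes
from re-running the search under score shuffles restricted to degree bins.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import fisher_enrichment
from .exceptions import ConfigurationError

__all__ = [
    "CrosstalkParams",
    "CrosstalkModule",
    "PermutationTest",
    "PathwayGraph",
    "score_nodes",
    "theta_from_quantile",
    "find_crosstalk",
    "permute_scores_within_degree_bins",
    "permutation_significance",
    "pathway_graph",
]


@dataclass(frozen=True)
class CrosstalkParams:
    theta_quantile: float = 0.98
    n_perm: int = 100
    degree_bin_width: int = 1
    exact_max_nodes: int = 15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 10:
            raise ConfigurationError("n_perm must be >= 10")
        if self.degree_bin_width < 1:
            raise ConfigurationError("degree_bin_width must be >= 1")
        if not (0.0 <= self.theta_quantile <= 1.0):
            raise ConfigurationError("theta_quantile must be in [0, 1]")


@dataclass
class CrosstalkModule:
    genes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    node_scores: dict[str, float]
    total_score: float
    p_perm: float | None = None
    p_extrapolated: float | None = None

    def subgraph(self, network: nx.Graph) -> nx.Graph:
        return network.subgraph(self.genes).copy()


@dataclass
class PermutationTest:
    p_empirical: float
    p_extrapolated: float
    null_totals: np.ndarray
    n_perm: int


def score_nodes(priority: pd.DataFrame, theta: float) -> pd.Series:
    """Shifted score ``rating - theta`` per gene (positive above threshold)."""
    if not (0.0 <= theta <= 5.0):
        raise ValueError(f"theta must be in [0, 5], got {theta}")
    return pd.Series(
        priority["rating"].to_numpy(dtype=float) - theta,
        index=priority["gene"].to_numpy(),
        name="score",
    )


def theta_from_quantile(priority: pd.DataFrame, quantile: float = 0.98) -> float:
    """Rating at the given quantile (default top-2% cut)."""
    return float(np.quantile(priority["rating"].to_numpy(dtype=float), quantile))


def _as_score_dict(network: nx.Graph, node_scores) -> dict[str, float]:
    scores = dict(node_scores.items() if hasattr(node_scores, "items") else node_scores)
    missing = sorted(set(network.nodes) - scores.keys())
    if missing:
        raise ValueError(f"scores missing for nodes: {missing[:5]}")
    return {g: float(scores[g]) for g in network.nodes}


def _module_from_nodes(
    network: nx.Graph, nodes: set[str], scores: dict[str, float]
) -> CrosstalkModule:
    sub = network.subgraph(nodes)
    genes = tuple(sorted(nodes))
    edges = tuple(sorted(tuple(sorted(e)) for e in sub.edges))
    node_scores = {g: scores[g] for g in genes}
    return CrosstalkModule(
        genes=genes,
        edges=edges,
        node_scores=node_scores,
        total_score=float(sum(node_scores.values())),
    )


def _exact_best_nodes(network: nx.Graph, scores: dict[str, float]) -> set[str]:
    """Enumerate all connected induced subgraphs (bitmask BFS); pick the max."""
    nodes = sorted(network.nodes)
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    adj = [0] * n
    for u, v in network.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    vals = [scores[g] for g in nodes]
    totals = np.zeros(1 << n)
    for mask in range(1, 1 << n):
        low = mask & -mask
        totals[mask] = totals[mask ^ low] + vals[low.bit_length() - 1]
    best_score = -np.inf
    best_mask = 0
    for mask in range(1, 1 << n):
        seen = mask & -mask
        frontier = seen
        while frontier:
            reach = 0
            m = frontier
            while m:
                b = m & -m
                reach |= adj[b.bit_length() - 1]
                m ^= b
            frontier = reach & mask & ~seen
            seen |= frontier
        if seen != mask:
            continue
        t = totals[mask]
        if t > best_score or (
            t == best_score and mask.bit_count() < best_mask.bit_count()
        ):
            best_score = t
            best_mask = mask
    return {nodes[i] for i in range(n) if best_mask >> i & 1}


def _best_subtree(tree: nx.Graph, scores: dict[str, float]) -> set[str]:
    """Exact max-weight connected subset of a tree (rooted DP)."""
    root = min(tree.nodes)
    dp: dict[str, float] = {}
    children: dict[str, list[str]] = defaultdict(list)
    order = []
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in tree.neighbors(u):
            if v not in seen:
                seen.add(v)
                children[u].append(v)
                stack.append(v)
    for u in reversed(order):
        dp[u] = scores[u] + sum(max(0.0, dp[c]) for c in children[u])
    best_root = min(tree.nodes, key=lambda u: (-dp[u], u))
    keep = {best_root}
    stack = [best_root]
    while stack:
        u = stack.pop()
        for c in children[u]:
            if dp[c] > 0:
                keep.add(c)
                stack.append(c)
    return keep


def _heuristic_nodes(network: nx.Graph, scores: dict[str, float]) -> set[str]:
    positives = {g for g in network.nodes if scores[g] > 0}
    pos_comps = sorted(sorted(c) for c in nx.connected_components(network.subgraph(positives)))

    # Penalty graph: traversing a negative node costs its score deficit.
    penalty = nx.Graph()
    penalty.add_nodes_from(network.nodes)
    for u, v in network.edges:
        w = max(0.0, -scores[u]) + max(0.0, -scores[v])
        penalty.add_edge(u, v, weight=w)

    comp_of = {}
    for ci, comp in enumerate(pos_comps):
        for g in comp:
            comp_of[g] = ci
    closure = nx.Graph()
    closure.add_nodes_from(range(len(pos_comps)))
    bridge_paths: dict[tuple[int, int], list[str]] = {}
    for ci, comp in enumerate(pos_comps):
        dist, path = nx.multi_source_dijkstra(penalty, set(comp), weight="weight")
        for cj in range(ci + 1, len(pos_comps)):
            reach = [g for g in pos_comps[cj] if g in dist]
            if not reach:
                continue
            gate = min(reach, key=lambda g: (dist[g], g))
            d = dist[gate]
            if not closure.has_edge(ci, cj) or d < closure[ci][cj]["weight"]:
                closure.add_edge(ci, cj, weight=d)
                bridge_paths[(ci, cj)] = path[gate]

    best_nodes: set[str] | None = None
    best_score = -np.inf
    for part in nx.connected_components(closure):
        cand: set[str] = set()
        for ci in part:
            cand.update(pos_comps[ci])
        mst = nx.minimum_spanning_tree(closure.subgraph(part), weight="weight")
        for ci, cj in mst.edges:
            key = (min(ci, cj), max(ci, cj))
            cand.update(bridge_paths[key])
        region = network.subgraph(cand)
        span = nx.maximum_spanning_tree(
            nx.Graph(
                (u, v, {"weight": scores[u] + scores[v]})
                for u, v in region.edges
            )
            if region.number_of_edges()
            else region,
        )
        if span.number_of_nodes() == 0:
            span = region.copy()
        keep = _best_subtree(span, scores)
        total = sum(scores[g] for g in keep)
        if total > best_score or (
            total == best_score
            and best_nodes is not None
            and tuple(sorted(keep)) < tuple(sorted(best_nodes))
        ):
            best_score = total
            best_nodes = keep
    assert best_nodes is not None
    return best_nodes


def find_crosstalk(
    network: nx.Graph,
    node_scores: Mapping[str, float] | pd.Series,
    params: CrosstalkParams | None = None,
) -> CrosstalkModule:
    """Connected subgraph maximizing the sum of node scores.

    Exact (exhaustive) for graphs up to ``params.exact_max_nodes`` nodes,
    heuristic above that. Raises if no node scores positive.
    """
    params = params or CrosstalkParams()
    scores = _as_score_dict(network, node_scores)
    if not any(s > 0 for s in scores.values()):
        raise ValueError("no signal above threshold: all node scores <= 0")
    if network.number_of_nodes() <= params.exact_max_nodes:
        nodes = _exact_best_nodes(network, scores)
    else:
        nodes = _heuristic_nodes(network, scores)
    return _module_from_nodes(network, nodes, scores)


def permute_scores_within_degree_bins(
    network: nx.Graph,
    node_scores: Mapping[str, float] | pd.Series,
    rng: np.random.Generator,
    degree_bin_width: int = 1,
) -> dict[str, float]:
    """Shuffle scores among nodes whose degrees fall in the same bin.

    With width 1 the bins hold exact degrees; singleton bins leave the score
    fixed (a documented no-op, not an error).
    """
    scores = _as_score_dict(network, node_scores)
    bins: dict[int, list[str]] = defaultdict(list)
    for g in sorted(network.nodes):
        bins[network.degree(g) // degree_bin_width].append(g)
    out: dict[str, float] = {}
    for key in sorted(bins):
        members = bins[key]
        vals = [scores[g] for g in members]
        order = rng.permutation(len(members))
        for g, j in zip(members, order):
            out[g] = vals[j]
    return out


def permutation_significance(
    network: nx.Graph,
    node_scores: Mapping[str, float] | pd.Series,
    observed_total: float,
    params: CrosstalkParams | None = None,
) -> PermutationTest:
    """Degree-preserving permutation test of the observed module score.

    Empirical p uses the +1 pseudocount (floor 1/(1+n_perm)); the normal-fit
    p is clearly an extrapolation beyond the permutation resolution.
    """
    params = params or CrosstalkParams()
    scores = _as_score_dict(network, node_scores)
    rng = np.random.default_rng(params.seed)
    null_totals = np.empty(params.n_perm)
    for i in range(params.n_perm):
        shuffled = permute_scores_within_degree_bins(
            network, scores, rng, params.degree_bin_width
        )
        null_totals[i] = find_crosstalk(network, shuffled, params).total_score
    p_emp = float((1 + np.sum(null_totals >= observed_total)) / (1 + params.n_perm))
    sd = null_totals.std(ddof=1) if params.n_perm > 1 else 0.0
    if sd > 0:
        p_ext = float(norm.sf((observed_total - null_totals.mean()) / sd))
    else:
        p_ext = 1.0 if observed_total <= null_totals.mean() else 0.0
    return PermutationTest(
        p_empirical=p_emp,
        p_extrapolated=p_ext,
        null_totals=null_totals,
        n_perm=params.n_perm,
    )


@dataclass
class PathwayGraph:
    nodes: pd.DataFrame  # pathway enrichment rows (significant only)
    edges: pd.DataFrame  # p1, p2, shared_count, mst_flag, shared_genes
    warnings: list[str] = field(default_factory=list)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def pathway_graph(
    crosstalk_genes,
    pathway_sets,
    universe,
    fdr_threshold: float = 0.05,
) -> PathwayGraph:
    """Pathway-centric view of a crosstalk module.

    Nodes are pathways over-represented in the crosstalk genes (Fisher FDR
    below threshold); candidate edges join pathways sharing at least one
    member gene (weight = shared count); only edges on the minimum spanning
    tree of the 1/shared_count distance are flagged as retained.
    """
    universe = frozenset(universe)
    query = frozenset(crosstalk_genes) & universe
    enr = fisher_enrichment(query, pathway_sets, universe)
    sig = enr[enr["FDR"] < fdr_threshold].reset_index(drop=True)
    msgs: list[str] = []
    if len(sig) < 2:
        msgs.append(f"only {len(sig)} significant pathway(s); graph has no edges")
        warnings.warn(msgs[-1], stacklevel=2)
        empty = pd.DataFrame(
            columns=["p1", "p2", "shared_count", "mst_flag", "shared_genes"]
        )
        return PathwayGraph(nodes=sig, edges=empty, warnings=msgs)
    ids = sorted(sig["set_id"])
    members = {pid: pathway_sets[pid].members & universe for pid in ids}
    cand = []
    for i, p1 in enumerate(ids):
        for p2 in ids[i + 1 :]:
            shared = sorted(members[p1] & members[p2])
            if shared:
                cand.append((p1, p2, len(shared), shared))
    # Kruskal on distance 1/shared_count, ties by lexicographic pathway pair
    cand.sort(key=lambda e: (1.0 / e[2], e[0], e[1]))
    uf = _UnionFind(ids)
    rows = []
    for p1, p2, count, shared in cand:
        rows.append(
            {
                "p1": p1,
                "p2": p2,
                "shared_count": count,
                "mst_flag": uf.union(p1, p2),
                "shared_genes": ",".join(shared),
            }
        )
    edges = pd.DataFrame(rows).sort_values(["p1", "p2"], ignore_index=True)
    return PathwayGraph(nodes=sig, edges=edges, warnings=msgs)
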
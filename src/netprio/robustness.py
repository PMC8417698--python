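"""Node-removal tolerance: single/combinatorial removal and targeted attack.

Disconnection is measured against the ORIGINAL node count N: after deleting a
removal set, nodes outside the largest remaining connected component count as
disconnected. Two conventions are provided — ``exclude_removed`` counts only
surviving nodes stranded outside the LCC, ``include_removed`` additionally
counts the removed nodes themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Mapping

import networkx as nx

__all__ = [
    "Convention",
    "RemovalResult",
    "AttackCurve",
    "removal_effect",
    "optimal_combination",
    "targeted_attack",
]

Convention = Literal["exclude_removed", "include_removed"]
_CONVENTIONS = ("exclude_removed", "include_removed")


@dataclass(frozen=True)
class RemovalResult:
    removed: tuple[str, ...]
    n_original: int
    n_disconnected: int
    fraction_disconnected: float
    lcc_size: int
    convention: str


@dataclass
class AttackCurve:
    ordering: str
    points: list[tuple[float, float]]  # (fraction_removed, fraction_disconnected)


def _lcc(graph: nx.Graph) -> list[str]:
    """Largest component; ties broken by the smallest member symbol."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    best = comps[0]
    for c in comps[1:]:
        if len(c) > len(best) or (len(c) == len(best) and c[0] < best[0]):
            best = c
    return best


def removal_effect(
    network: nx.Graph,
    remove_set: Iterable[str],
    convention: Convention = "exclude_removed",
) -> RemovalResult:
    """Fraction of the original N nodes disconnected after deleting a set."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    removed = frozenset(remove_set)
    unknown = sorted(removed - set(network.nodes))
    if unknown:
        raise ValueError(f"remove_set contains unknown nodes: {unknown[:5]}")
    n = network.number_of_nodes()
    if len(removed) == n:
        raise ValueError("cannot remove every node")
    rest = network.subgraph(set(network.nodes) - removed)
    lcc = _lcc(rest)
    n_disc = rest.number_of_nodes() - len(lcc)
    if convention == "include_removed":
        n_disc += len(removed)
    return RemovalResult(
        removed=tuple(sorted(removed)),
        n_original=n,
        n_disconnected=n_disc,
        fraction_disconnected=n_disc / n,
        lcc_size=len(lcc),
        convention=convention,
    )


def optimal_combination(
    network: nx.Graph,
    candidates: Iterable[str],
    k_min: int = 1,
    k_max: int = 4,
    convention: Convention = "exclude_removed",
    max_combinations: int = 1_000_000,
) -> dict[int, list[RemovalResult]]:
    """Exhaustive search for the most disruptive size-k candidate subsets.

    Returns, for every k in [k_min, k_max], all tied argmax removal results
    (sorted by removed tuple). Refuses budgets above ``max_combinations``.
    """
    cand = sorted(set(candidates))
    if not (1 <= k_min <= k_max <= len(cand)):
        raise ValueError("need 1 <= k_min <= k_max <= len(candidates)")
    total = sum(comb(len(cand), k) for k in range(k_min, k_max + 1))
    if total > max_combinations:
        raise ValueError(
            f"{total} combinations exceed the budget of {max_combinations}; "
            "reduce k_max/candidates or use a beam-search variant"
        )
    out: dict[int, list[RemovalResult]] = {}
    for k in range(k_min, k_max + 1):
        best: list[RemovalResult] = []
        best_frac = -1.0
        for subset in combinations(cand, k):
            res = removal_effect(network, subset, convention)
            if res.fraction_disconnected > best_frac + 1e-12:
                best = [res]
                best_frac = res.fraction_disconnected
            elif abs(res.fraction_disconnected - best_frac) <= 1e-12:
                best.append(res)
        out[k] = sorted(best, key=lambda r: r.removed)
    return out


def targeted_attack(
    network: nx.Graph,
    ordering: Literal["degree", "betweenness", "priority"] = "degree",
    score_vector: Mapping[str, float] | None = None,
    convention: Convention = "exclude_removed",
) -> AttackCurve:
    """Sequential removal in a statically precomputed order.

    The ordering statistic (degree, unweighted shortest-path betweenness, or
    a supplied priority score) is computed once on the intact network; ties
    break by gene symbol. Points are recorded after each single removal up to
    N - 1 removals.
    """
    n = network.number_of_nodes()
    if ordering == "degree":
        stat = dict(network.degree())
    elif ordering == "betweenness":
        stat = nx.betweenness_centrality(network, normalized=True)
    elif ordering == "priority":
        if score_vector is None:
            raise ValueError("ordering='priority' requires score_vector")
        stat = {g: float(score_vector[g]) for g in network.nodes}
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    order = sorted(network.nodes, key=lambda g: (-stat[g], g))
    points: list[tuple[float, float]] = []
    removed: set[str] = set()
    for g in order[: n - 1]:
        removed.add(g)
        res = removal_effect(network, removed, convention)
        points.append((len(removed) / n, res.fraction_disconnected))
    return AttackCurve(ordering=ordering, points=points)
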
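"""Evidence combination, restart-walk propagation, and 0-5 priority ratings.

The propagation operates on the column-normalized adjacency of an undirected
gene network: the fixed point of ``p <- (1 - r) * W @ p + r * p0`` with
restart probability ``r`` and seed vector ``p0``. Ratings map average-tie
affinity ranks linearly onto the 0-5 scale (top gene -> 5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .exceptions import ConfigurationError

__all__ = [
    "RWRParams",
    "PropagationResult",
    "combine_evidence",
    "propagate",
    "rate",
    "top_fraction",
]

EVIDENCE_LAYERS = ("nGene", "eGene", "cGene")


@dataclass(frozen=True)
class RWRParams:
    """Parameters of the restart-walk propagation."""

    restart: float = 0.75
    tol: float = 1e-10
    max_iter: int = 10_000
    layer_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ConfigurationError(f"restart must be in (0, 1], got {self.restart}")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.layer_weights is not None:
            for name, w in self.layer_weights.items():
                if w < 0:
                    raise ConfigurationError(f"negative weight for layer {name!r}")


@dataclass
class PropagationResult:
    affinity: pd.Series
    converged: bool
    n_iter: int
    residual: float
    warnings: list[str] = field(default_factory=list)


def _evidence_matrix(evidence: pd.DataFrame) -> pd.DataFrame:
    """Return evidence indexed by gene with numeric layer columns only."""
    df = evidence
    if "gene" in df.columns:
        if df["gene"].duplicated().any():
            dupes = sorted(df.loc[df["gene"].duplicated(), "gene"].unique())
            raise ValueError(f"duplicate genes in evidence table: {dupes[:5]}")
        df = df.set_index("gene")
    layers = df.select_dtypes(include=[np.number])
    values = layers.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("evidence scores must be finite")
    if (values < 0).any():
        raise ValueError("evidence scores must be non-negative")
    return layers


def combine_evidence(
    evidence: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> pd.Series:
    """Weighted sum of evidence layers, normalized to a seed distribution.

    All-zero evidence degenerates to the uniform distribution. Missing or
    negative weights raise :class:`ConfigurationError`.
    """
    layers = _evidence_matrix(evidence)
    if weights is None:
        weights = {c: 1.0 for c in layers.columns}
    missing = [c for c in layers.columns if c not in weights]
    if missing:
        raise ConfigurationError(f"weights missing for layers: {missing}")
    for name, w in weights.items():
        if w < 0:
            raise ConfigurationError(f"negative weight for layer {name!r}")
    w = np.array([float(weights[c]) for c in layers.columns])
    raw = layers.to_numpy(dtype=float) @ w
    total = raw.sum()
    if total <= 0:
        seeds = np.full(len(layers), 1.0 / len(layers))
    else:
        seeds = raw / total
    return pd.Series(seeds, index=layers.index, name="seed")


def _propagate_component(
    graph: nx.Graph, nodes: list[str], p0: np.ndarray, params: RWRParams
) -> tuple[np.ndarray, bool, int, float]:
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=float)
    degrees = np.asarray(adj.sum(axis=0)).ravel()
    # column-normalize: W[:, j] = A[:, j] / deg(j)
    w_mat = adj @ sp.diags(1.0 / degrees)
    r = params.restart
    p = p0.copy()
    for it in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (w_mat @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < params.tol:
            return p, True, it, residual
    return p, False, params.max_iter, residual


def propagate(
    network: nx.Graph, seeds: pd.Series, params: RWRParams | None = None
) -> PropagationResult:
    """Run the restart walk to its fixed point.

    Seeds must be a probability vector over the network's nodes. Disconnected
    networks are handled per component (seed mass is conserved within each
    component); isolated nodes retain their seed mass. Non-convergence sets
    ``converged=False`` and emits a warning instead of raising.
    """
    params = params or RWRParams()
    nodes = sorted(network.nodes)
    if set(seeds.index) != set(nodes):
        raise ValueError("seeds must cover exactly the network nodes")
    p0 = seeds.reindex(nodes).to_numpy(dtype=float)
    if not np.all(np.isfinite(p0)) or (p0 < 0).any():
        raise ValueError("seeds must be finite and non-negative")
    if abs(p0.sum() - 1.0) > 1e-6:
        raise ValueError(f"seeds must sum to 1 (got {p0.sum():.6g})")

    if params.restart == 1.0:  # restart-only limit: exact identity
        return PropagationResult(
            affinity=pd.Series(p0, index=nodes, name="affinity"),
            converged=True,
            n_iter=0,
            residual=0.0,
        )

    index_of = {g: i for i, g in enumerate(nodes)}
    p = np.zeros_like(p0)
    converged = True
    n_iter = 0
    residual = 0.0
    msgs: list[str] = []
    for comp in nx.connected_components(network):
        comp_nodes = sorted(comp)
        idx = np.array([index_of[g] for g in comp_nodes])
        if len(comp_nodes) == 1:
            p[idx] = p0[idx]  # isolated node keeps its seed mass
            continue
        pc, ok, it, res = _propagate_component(network, comp_nodes, p0[idx], params)
        p[idx] = pc
        n_iter = max(n_iter, it)
        residual = max(residual, res)
        if not ok:
            converged = False
    if not converged:
        msgs.append(
            f"propagation did not converge in {params.max_iter} iterations "
            f"(residual {residual:.3g})"
        )
        warnings.warn(msgs[-1], RuntimeWarning, stacklevel=2)
    return PropagationResult(
        affinity=pd.Series(p, index=nodes, name="affinity"),
        converged=converged,
        n_iter=n_iter,
        residual=residual,
        warnings=msgs,
    )


def rate(affinity: pd.Series) -> pd.DataFrame:
    """Convert affinities to a priority table (gene, rating, rank, affinity).

    rating = 5 * (N - avg_rank + 1) / N with average-tie ranking, so the top
    gene approaches 5 and the bottom 5/N. The integer ``rank`` column breaks
    ties deterministically by gene symbol.
    """
    values = affinity.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or (values < 0).any():
        raise ValueError("affinity must be finite and non-negative")
    n = len(values)
    avg_rank = rankdata(-values, method="average")
    rating = 5.0 * (n - avg_rank + 1.0) / n
    order = sorted(range(n), key=lambda i: (-values[i], str(affinity.index[i])))
    rank = np.empty(n, dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    table = pd.DataFrame(
        {
            "gene": affinity.index.astype(str),
            "rating": rating,
            "rank": rank,
            "affinity": values,
        }
    )
    return table.sort_values("rank", ignore_index=True)


def top_fraction(priority: pd.DataFrame, fraction: float) -> list[str]:
    """Top ``round(fraction * N)`` genes by rank (round half away from zero)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(priority)
    m = int(math.floor(fraction * n + 0.5))
    if m == 0:
        raise ValueError(f"fraction {fraction} selects zero of {n} genes")
    ordered = priority.sort_values("rank")
    return ordered["gene"].head(m).tolist()
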
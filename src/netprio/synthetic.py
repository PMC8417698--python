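"""Synthetic pipeline inputs with planted, recoverable ground truth.

Everything downstream consumes these emulated processed inputs: a
degree-heterogeneous interaction network with evidence-tagged edges, a
connected high-evidence module, gene sets oversampling the module, a
phase-annotated drug table, correlated multi-disease priority profiles, and
sparse binary tractability labels. A single run seed drives fixed per-stage
sub-seeds so components stay decoupled but byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .genesets import GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "SyntheticDataset",
    "generate_network",
    "plant_module",
    "generate_evidence",
    "generate_genesets",
    "generate_drug_table",
    "generate_disease_profiles",
    "generate_tractability",
    "simulate",
]

EVIDENCE_TAGS = ("experiments", "databases")
_LAYERS = ("nGene", "eGene", "cGene")

# fixed sub-seed offsets, one per generator
_SUB = {
    "network": 11,
    "module": 23,
    "evidence": 37,
    "genesets": 41,
    "drugs": 53,
    "diseases": 67,
    "tractability": 79,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 500
    network_model: str = "preferential_attachment"
    mean_degree: float = 4.0
    module_size: int = 20
    evidence_effect: float = 3.0
    noise_sd: float = 1.0
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 40)
    n_enriched_sets: int = 5
    n_diseases: int = 6
    shared_signal_fraction: float = 0.5
    tractable_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.module_size < 1:
            raise ConfigurationError("n_genes and module_size must be positive")
        if self.module_size > self.n_genes:
            raise ConfigurationError("module_size cannot exceed n_genes")
        if self.network_model not in ("preferential_attachment", "configuration"):
            raise ConfigurationError(
                f"unknown network_model {self.network_model!r}"
            )
        lo, hi = self.set_size_range
        if lo > hi or lo < 1:
            raise ConfigurationError("set_size_range must satisfy 1 <= low <= high")
        for name in ("shared_signal_fraction", "tractable_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.evidence_effect < 0 or self.noise_sd < 0:
            raise ConfigurationError("evidence_effect and noise_sd must be >= 0")
        if self.mean_degree <= 0:
            raise ConfigurationError("mean_degree must be positive")
        if self.n_enriched_sets > self.n_sets:
            raise ConfigurationError("n_enriched_sets cannot exceed n_sets")


@dataclass(frozen=True)
class PlantedTruth:
    module_genes: frozenset[str]
    enriched_set_ids: tuple[str, ...] = ()
    true_drug_targets: frozenset[str] = frozenset()


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    network: nx.Graph
    truth: PlantedTruth
    evidence: pd.DataFrame
    genesets: GeneSetCollection
    drugs: pd.DataFrame
    disease_profiles: pd.DataFrame
    tractability: pd.DataFrame


def _rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _SUB[stage]])


def _gene_name(i: int) -> str:
    return f"G{i + 1:05d}"


def generate_network(config: SyntheticConfig) -> nx.Graph:
    """Simple, connected, evidence-tagged undirected gene network."""
    if config.n_genes < 10:
        raise ValueError("need n_genes >= 10")
    rng = _rng(config, "network")
    n = config.n_genes
    if config.network_model == "preferential_attachment":
        m = max(1, int(round(config.mean_degree / 2.0)))
        m = min(m, n - 1)
        graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    else:
        degrees = rng.poisson(config.mean_degree, size=n).clip(min=1)
        if degrees.sum() % 2:
            degrees[0] += 1
        multigraph = nx.configuration_model(
            degrees.tolist(), seed=int(rng.integers(2**31))
        )
        graph = nx.Graph(multigraph)
        graph.remove_edges_from(nx.selfloop_edges(graph))
    # bridge disconnected parts into one component
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    anchor = comps[0]
    for comp in comps[1:]:
        u = rng.choice(sorted(anchor))
        v = rng.choice(sorted(comp))
        graph.add_edge(int(u), int(v))
        anchor |= comp
    graph = nx.relabel_nodes(graph, {i: _gene_name(i) for i in graph.nodes})
    for u, v in sorted(graph.edges):
        graph.edges[u, v]["evidence"] = EVIDENCE_TAGS[int(rng.integers(2))]
    return graph


def plant_module(
    network: nx.Graph, module_size: int, rng: np.random.Generator
) -> PlantedTruth:
    """Grow a connected module by uniform sampling over the BFS frontier."""
    nodes = sorted(network.nodes)
    if module_size > len(nodes):
        raise ValueError("module_size exceeds node count")
    start = str(rng.choice(nodes))
    chosen = {start}
    frontier = set(network.neighbors(start)) - chosen
    while len(chosen) < module_size and frontier:
        pick = str(rng.choice(sorted(frontier)))
        chosen.add(pick)
        frontier |= set(network.neighbors(pick))
        frontier -= chosen
    return PlantedTruth(module_genes=frozenset(chosen))


def generate_evidence(
    network: nx.Graph, truth: PlantedTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Three half-normal evidence layers; planted genes get a mean uplift
    in a randomly chosen subset of layers (at least two of the three, so the
    combined signal separates from the summed background noise)."""
    missing = truth.module_genes - set(network.nodes)
    if missing:
        raise ValueError(f"planted genes absent from network: {sorted(missing)[:5]}")
    rng = _rng(config, "evidence")
    genes = sorted(network.nodes)
    values = np.abs(rng.normal(0.0, config.noise_sd, size=(len(genes), len(_LAYERS))))
    planted = truth.module_genes
    for i, g in enumerate(genes):
        if g in planted:
            n_layers = int(rng.integers(2, len(_LAYERS) + 1))
            mask = np.zeros(len(_LAYERS), dtype=bool)
            mask[rng.choice(len(_LAYERS), size=n_layers, replace=False)] = True
            values[i, mask] += config.evidence_effect
    table = pd.DataFrame(values, columns=list(_LAYERS))
    table.insert(0, "gene", genes)
    return table


def generate_genesets(
    genes: Iterable[str],
    truth: PlantedTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, tuple[str, ...]]:
    """GMT-style sets; the first ``n_enriched_sets`` oversample planted genes."""
    genes = sorted(genes)
    module = sorted(truth.module_genes)
    background = [g for g in genes if g not in truth.module_genes]
    lo, hi = config.set_size_range
    sets = []
    enriched_ids = []
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        set_id = f"S{i + 1:04d}"
        if i < config.n_enriched_sets and module:
            n_mod = min(len(module), max(1, size // 2))
            picked = list(rng.choice(module, size=n_mod, replace=False))
            n_bg = min(size - n_mod, len(background))
            if n_bg > 0:
                picked += list(rng.choice(background, size=n_bg, replace=False))
            enriched_ids.append(set_id)
            desc = "planted-enriched synthetic set"
        else:
            picked = list(rng.choice(genes, size=size, replace=False))
            desc = "background synthetic set"
        sets.append((set_id, desc, picked))
    return GeneSetCollection(sets), tuple(enriched_ids)


_INDICATIONS = ("renal", "inflammation", "oncology", "metabolic")
_MOA = ("inhibitor", "agonist", "antagonist", "antibody")


def generate_drug_table(
    genes: Iterable[str], truth: PlantedTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Phase-annotated drug-target rows; module-concentrated true targets."""
    genes = sorted(genes)
    module = sorted(truth.module_genes)
    background = [g for g in genes if g not in truth.module_genes]
    n_true = min(12, len(module)) or 1
    true_targets = sorted(rng.choice(module or genes, size=n_true, replace=False))
    n_bg = min(n_true, len(background))
    bg_targets = sorted(rng.choice(background, size=n_bg, replace=False)) if n_bg else []
    rows = []
    serial = 0
    for gene in true_targets + bg_targets:
        for _ in range(int(rng.integers(1, 4))):
            serial += 1
            rows.append(
                {
                    "gene": gene,
                    "drug": f"drug_{serial:04d}",
                    "phase": int(rng.integers(1, 5)),
                    "indication": _INDICATIONS[int(rng.integers(len(_INDICATIONS)))],
                    "moa": _MOA[int(rng.integers(len(_MOA)))],
                }
            )
    table = pd.DataFrame(rows).drop_duplicates(["gene", "drug", "indication"])
    return table.sort_values(["gene", "drug"], ignore_index=True), frozenset(true_targets)


def generate_disease_profiles(
    genes: Iterable[str],
    truth: PlantedTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Priority-rating-like gene x disease matrix in [0, 5].

    A shared fraction of planted genes is elevated in every disease; the rest
    of the module is elevated in the first (focal) disease only.
    """
    genes = sorted(genes)
    module = sorted(truth.module_genes)
    n_shared = int(round(config.shared_signal_fraction * len(module)))
    shared = set(module[:n_shared])
    focal_only = set(module[n_shared:])
    cols = [f"D{i + 1}" for i in range(config.n_diseases)]
    base = np.abs(rng.normal(1.0, 0.8, size=(len(genes), config.n_diseases)))
    for i, g in enumerate(genes):
        if g in shared:
            base[i, :] += 2.5
        elif g in focal_only:
            base[i, 0] += 2.5
    table = pd.DataFrame(np.clip(base, 0.0, 5.0), columns=cols)
    table.insert(0, "gene", genes)
    return table


def generate_tractability(
    genes: Iterable[str], rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Binary tractability labels at approximately the requested rate."""
    if not (0.0 <= rate <= 1.0):
        raise ConfigurationError("rate must be in [0, 1]")
    genes = sorted(genes)
    tractable = rng.random(len(genes)) < rate
    n_pockets = np.where(tractable, rng.poisson(1.5, size=len(genes)) + 1, 0)
    structures = [
        ",".join(f"X{int(rng.integers(1000, 9999)):04d}" for _ in range(min(2, p)))
        if p
        else ""
        for p in n_pockets
    ]
    return pd.DataFrame(
        {
            "gene": genes,
            "tractable": tractable.astype(int),
            "n_pockets": n_pockets.astype(int),
            "structures": structures,
        }
    )


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full input bundle with a composed planted truth."""
    network = generate_network(config)
    truth = plant_module(network, config.module_size, _rng(config, "module"))
    evidence = generate_evidence(network, truth, config)
    genes = sorted(network.nodes)
    genesets, enriched_ids = generate_genesets(
        genes, truth, config, _rng(config, "genesets")
    )
    drugs, true_targets = generate_drug_table(genes, truth, _rng(config, "drugs"))
    profiles = generate_disease_profiles(genes, truth, config, _rng(config, "diseases"))
    tract = generate_tractability(genes, config.tractable_rate, _rng(config, "tractability"))
    truth = replace(
        truth, enriched_set_ids=enriched_ids, true_drug_targets=true_targets
    )
    return SyntheticDataset(
        config=config,
        network=network,
        truth=truth,
        evidence=evidence,
        genesets=genesets,
        drugs=drugs,
        disease_profiles=profiles,
        tractability=tract,
    )
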
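"""Readers/writers for the package's TSV, GMT, and JSON interchange formats.

All writers emit deterministic row order (sorted keys) so outputs diff
cleanly; TSV is UTF-8 with '.' decimals and empty fields for NA.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .exceptions import MalformedInputError
from .genesets import GeneSetCollection
from .synthetic import PlantedTruth, SyntheticDataset

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "read_truth",
    "write_truth",
    "write_dataset",
]

_EDGE_HEADERS = {"gene_a", "gene_b", "source", "target", "from", "to"}


def read_edge_list(path: str | Path) -> nx.Graph:
    """Undirected simple graph from a 2-3 column TSV (optional sniffed header).

    Duplicate edges (either orientation) and self-loops are dropped with a
    counted warning; malformed rows raise with their line number.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self = n_dup = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MalformedInputError(
                    f"{path.name}:{lineno}: expected >= 2 tab-separated fields"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (a.lower() in _EDGE_HEADERS or b.lower() in _EDGE_HEADERS):
                continue  # header row
            if not a or not b:
                raise MalformedInputError(f"{path.name}:{lineno}: empty gene symbol")
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            attrs = {}
            if len(fields) >= 3 and fields[2].strip():
                attrs["evidence"] = fields[2].strip()
            graph.add_edge(a, b, **attrs)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop row(s)", stacklevel=2)
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate edge row(s)", stacklevel=2)
    return graph


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Canonical form: endpoints sorted within a row, rows sorted."""
    rows = sorted(
        (min(u, v), max(u, v), str(data.get("evidence", "")))
        for u, v, data in network.edges(data=True)
    )
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tevidence\n")
        for a, b, tag in rows:
            fh.write(f"{a}\t{b}\t{tag}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT: ``set_id <TAB> description <TAB> member...`` per line."""
    path = Path(path)
    sets = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedInputError(
                    f"{path.name}:{lineno}: GMT line needs id, description, members"
                )
            members = [g.strip() for g in fields[2:] if g.strip()]
            sets.append((fields[0].strip(), fields[1].strip(), members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for set_id in sorted(collection):
            gs = collection[set_id]
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.set_id}\t{gs.description}\t{members}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV table (header required, empty fields as NA)."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str}, keep_default_na=True)


def write_table(table: pd.DataFrame, path: str | Path, sort_by=None) -> None:
    out = table
    if sort_by:
        out = table.sort_values(sort_by, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "module_genes": sorted(truth.module_genes),
        "enriched_set_ids": list(truth.enriched_set_ids),
        "true_drug_targets": sorted(truth.true_drug_targets),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PlantedTruth(
        module_genes=frozenset(payload["module_genes"]),
        enriched_set_ids=tuple(payload["enriched_set_ids"]),
        true_drug_targets=frozenset(payload["true_drug_targets"]),
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all synthetic inputs into ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "evidence": outdir / "evidence.tsv",
        "genesets": outdir / "genesets.gmt",
        "drugs": outdir / "drugs.tsv",
        "disease_profiles": outdir / "disease_profiles.tsv",
        "tractability": outdir / "tractability.tsv",
        "truth": outdir / "truth.json",
    }
    write_edge_list(dataset.network, paths["network"])
    write_table(dataset.evidence, paths["evidence"], sort_by="gene")
    write_gmt(dataset.genesets, paths["genesets"])
    write_table(dataset.drugs, paths["drugs"], sort_by=["gene", "drug"])
    write_table(dataset.disease_profiles, paths["disease_profiles"], sort_by="gene")
    write_table(dataset.tractability, paths["tractability"], sort_by="gene")
    write_truth(dataset.truth, paths["truth"])
    return paths


def genes_of(table: pd.DataFrame) -> list[str]:
    """Sorted gene column of any per-gene table."""
    return sorted(table["gene"].astype(str))


def edges_of(network: nx.Graph) -> Iterable[tuple[str, str]]:
    return sorted((min(u, v), max(u, v)) for u, v in network.edges)
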
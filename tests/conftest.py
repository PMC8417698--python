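import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprio import prioritize as pz
from netprio.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic bundle shared by read-only tests."""
    return simulate(SyntheticConfig(n_genes=150, module_size=12, seed=11))


@pytest.fixture(scope="session")
def small_priority(small_dataset):
    ds = small_dataset
    seeds = pz.combine_evidence(ds.evidence)
    result = pz.propagate(ds.network, seeds)
    return pz.rate(result.affinity)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


@pytest.fixture
def star_graph():
    g = nx.star_graph(9)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def toy_priority(ratings: dict[str, float]) -> pd.DataFrame:
    """Priority table from explicit ratings (rank = rating order)."""
    genes = sorted(ratings, key=lambda g: (-ratings[g], g))
    return pd.DataFrame(
        {
            "gene": genes,
            "rating": [ratings[g] for g in genes],
            "rank": np.arange(1, len(genes) + 1),
            "affinity": np.linspace(1, 0.1, len(genes)) / np.linspace(1, 0.1, len(genes)).sum(),
        }
    )
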
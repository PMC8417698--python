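"""Supra-hexagonal self-organizing map for cross-disease profile comparison.

The map is a hexagon of hexagons: a central unit plus concentric rings, so a
radius-r map holds ``1 + sum_{i<r} 6i`` units (19 at radius 3). Codebook
vectors live in disease-profile space; training is the classic sequential
best-matching-unit update with a Gaussian neighborhood on hex-grid distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .enrichment import fisher_enrichment
from .exceptions import ConfigurationError
from .genesets import GeneSetCollection

__all__ = [
    "SOMParams",
    "SupraHexMap",
    "hex_distance",
    "build_map",
    "train_som",
    "cluster_map",
    "overlay_binary",
    "disease_correlations",
    "tractability_enrichment",
]

# axial-coordinate neighbor steps, pinned order (ring walks start "south-west")
_HEX_DIRS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


def hex_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Hex-grid (cube) distance between two axial coordinates."""
    dq, dr = a[0] - b[0], a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def _spiral_coords(radius: int) -> list[tuple[int, int]]:
    coords = [(0, 0)]
    for ring in range(1, radius):
        q, r = _HEX_DIRS[4][0] * ring, _HEX_DIRS[4][1] * ring
        for direction in _HEX_DIRS:
            for _ in range(ring):
                coords.append((q, r))
                q, r = q + direction[0], r + direction[1]
    return coords


@dataclass(frozen=True)
class SOMParams:
    epochs: int = 60
    alpha0: float = 0.5
    sigma0: float | None = None  # defaults to the map radius
    decay: str = "linear"
    k_clusters: int = 4
    seed: int | None = None
    batch: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha0 <= 1.0):
            raise ConfigurationError("alpha0 must be in (0, 1]")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ConfigurationError("sigma0 must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.decay not in ("linear", "exponential"):
            raise ConfigurationError(f"unknown decay schedule {self.decay!r}")


@dataclass
class SupraHexMap:
    radius: int
    coords: tuple[tuple[int, int], ...]  # axial (q, r), spiral order, H1 = center
    codebook: np.ndarray | None = None  # (n_hex, n_diseases)
    diseases: tuple[str, ...] | None = None
    bmu: pd.Series | None = None  # gene -> 1-based hexagon index
    clusters: np.ndarray | None = None  # 1-based labels, len n_hex
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_hex(self) -> int:
        return len(self.coords)

    def grid_distances(self) -> np.ndarray:
        n = self.n_hex
        d = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = hex_distance(self.coords[i], self.coords[j])
        return d

    def neighbors(self, index: int) -> list[int]:
        """1-based indices of hexagons at unit distance from ``index``."""
        c = self.coords[index - 1]
        return [
            j + 1
            for j, other in enumerate(self.coords)
            if hex_distance(c, other) == 1
        ]


def build_map(radius: int) -> SupraHexMap:
    """Untrained supra-hexagonal lattice (1 + 6 + 12 + ... hexagons)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return SupraHexMap(radius=radius, coords=tuple(_spiral_coords(radius)))


def _profiles_matrix(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    df = profiles.set_index("gene") if "gene" in profiles.columns else profiles
    x = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("profile matrix contains non-finite values")
    return x, [str(g) for g in df.index], [str(c) for c in df.columns]


def _init_codebook(
    smap: SupraHexMap, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """PCA-plane linear initialization; seeded random fallback on degeneracy."""
    n_hex = smap.n_hex
    mean = x.mean(axis=0)
    centered = x - mean
    # cartesian embedding of the axial coordinates, scaled to [-1, 1]
    cart = np.array(
        [(q + r / 2.0, r * np.sqrt(3) / 2.0) for q, r in smap.coords]
    )
    span = np.abs(cart).max(axis=0)
    span[span == 0] = 1.0
    cart = cart / span
    try:
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover
        s = np.zeros(1)
        vt = np.zeros((1, x.shape[1]))
    scale = s / max(1.0, np.sqrt(x.shape[0]))
    if len(s) >= 2 and s[1] > 1e-12:
        return (
            mean
            + np.outer(cart[:, 0] * scale[0], vt[0])
            + np.outer(cart[:, 1] * scale[1], vt[1])
        )
    sd = centered.std(axis=0)
    sd[sd == 0] = 1e-3
    return mean + rng.normal(0.0, 1.0, size=(n_hex, x.shape[1])) * sd


def _schedules(params: SOMParams, radius: int) -> tuple[np.ndarray, np.ndarray]:
    T = params.epochs
    sigma0 = params.sigma0 if params.sigma0 is not None else float(max(radius, 1))
    rough = max(1, T // 2)
    fine = T - rough
    if params.decay == "linear":
        sig_rough = np.linspace(sigma0, 1.0, rough)
        sig_fine = np.linspace(1.0, 0.5, fine) if fine else np.empty(0)
        alphas = np.linspace(params.alpha0, 0.01, T)
    else:  # exponential
        sig_rough = sigma0 * (1.0 / sigma0) ** (np.arange(rough) / max(1, rough - 1))
        sig_fine = 1.0 * 0.5 ** (np.arange(1, fine + 1) / max(1, fine)) if fine else np.empty(0)
        alphas = params.alpha0 * (0.01 / params.alpha0) ** (np.arange(T) / max(1, T - 1))
    return np.concatenate([sig_rough, sig_fine]), alphas


def train_som(
    smap: SupraHexMap, profiles: pd.DataFrame, params: SOMParams | None = None
) -> SupraHexMap:
    """Train the codebook on gene x disease profiles; returns a new map.

    Gene order is reshuffled each epoch from the run seed (sequential mode);
    batch mode recomputes all assignments per epoch. Quantization error (mean
    gene-to-BMU distance) is recorded after every epoch.
    """
    params = params or SOMParams()
    x, genes, diseases = _profiles_matrix(profiles)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 disease columns")
    if x.shape[0] < smap.n_hex:
        warnings.warn(
            f"{x.shape[0]} genes for {smap.n_hex} hexagons; map may be sparse",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    codebook = _init_codebook(smap, x, rng).astype(float)
    grid = smap.grid_distances().astype(float)
    sigmas, alphas = _schedules(params, smap.radius)
    qe_history: list[float] = []
    n = x.shape[0]
    for epoch in range(params.epochs):
        sigma, alpha = sigmas[epoch], alphas[epoch]
        kernel = np.exp(-(grid**2) / (2.0 * sigma**2))
        if params.batch:
            d = np.linalg.norm(x[:, None, :] - codebook[None, :, :], axis=2)
            bmus = d.argmin(axis=1)
            h = kernel[:, bmus]  # (n_hex, n_genes)
            denom = h.sum(axis=1, keepdims=True)
            denom[denom == 0] = 1.0
            codebook = (h @ x) / denom
        else:
            for g in rng.permutation(n):
                diff = x[g] - codebook
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                codebook += alpha * kernel[bmu][:, None] * diff
        d = np.linalg.norm(x[:, None, :] - codebook[None, :, :], axis=2)
        qe_history.append(float(d.min(axis=1).mean()))
    d = np.linalg.norm(x[:, None, :] - codebook[None, :, :], axis=2)
    bmu = pd.Series(d.argmin(axis=1) + 1, index=genes, name="bmu")
    return replace(
        smap,
        codebook=codebook,
        diseases=tuple(diseases),
        bmu=bmu,
        qe_history=qe_history,
        clusters=None,
    )


def _label_regions(smap: SupraHexMap, labels: np.ndarray, label: int) -> list[set[int]]:
    """Connected regions (0-based hex indices) carrying ``label``."""
    pool = {i for i in range(smap.n_hex) if labels[i] == label}
    regions = []
    while pool:
        start = min(pool)
        region = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v1 in smap.neighbors(u + 1):
                v = v1 - 1
                if v in pool and v not in region:
                    region.add(v)
                    stack.append(v)
        regions.append(region)
        pool -= region
    return regions


def cluster_map(smap: SupraHexMap, k: int) -> np.ndarray:
    """Average-linkage clustering of codebook vectors into contiguous regions.

    Hexagons stranded outside their cluster's main (largest) region are
    reassigned to the adjacent settled cluster with the nearest codebook
    vector, guaranteeing each cluster covers contiguous hexagons.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if smap.codebook is None:
        raise ValueError("map is untrained")
    n = smap.n_hex
    if k > n:
        raise ValueError(f"k={k} exceeds {n} hexagons")
    if k == n:
        labels = np.arange(1, n + 1)
    elif k == 1:
        labels = np.ones(n, dtype=int)
    else:
        z = linkage(smap.codebook, method="average")
        labels = fcluster(z, t=k, criterion="maxclust")
    # contiguity repair
    for _ in range(n):
        main: dict[int, set[int]] = {}
        for lab in sorted(set(labels)):
            regions = _label_regions(smap, labels, lab)
            main[lab] = max(regions, key=lambda r: (len(r), -min(r)))
        settled = set().union(*main.values())
        strays = [i for i in range(n) if i not in settled]
        if not strays:
            break
        moved = False
        for i in strays:
            options = []
            for j1 in smap.neighbors(i + 1):
                j = j1 - 1
                if j in settled:
                    dist = float(
                        np.linalg.norm(smap.codebook[i] - smap.codebook[j])
                    )
                    options.append((dist, labels[j]))
            if options:
                labels[i] = min(options)[1]
                moved = True
        if not moved:  # pragma: no cover - map is connected, cannot happen
            break
    # relabel 1..k' by first (smallest) hexagon index per cluster
    order = sorted(set(labels), key=lambda lab: int(np.argmax(labels == lab)))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels], dtype=int)
    smap.clusters = labels
    return labels


def overlay_binary(
    smap: SupraHexMap, tract: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-hexagon tractability probability and pooled per-cluster percentage.

    Probability = tractable/mapped genes in the hexagon (NaN when empty);
    cluster percentages pool counts over member hexagons.
    """
    if smap.bmu is None:
        raise ValueError("map is untrained")
    status = (
        tract.set_index("gene")["tractable"] if "gene" in tract.columns else tract["tractable"]
    )
    mapped = smap.bmu
    missing = sorted(set(mapped.index) - set(status.index))
    if missing:
        warnings.warn(
            f"{len(missing)} mapped gene(s) missing tractability; excluded",
            stacklevel=2,
        )
    kept = mapped[mapped.index.isin(status.index)]
    rows = []
    for h in range(1, smap.n_hex + 1):
        genes = kept.index[kept == h]
        n_genes = len(genes)
        n_tract = int(status.loc[genes].astype(bool).sum()) if n_genes else 0
        rows.append(
            {
                "hex_index": h,
                "n_genes": n_genes,
                "n_tractable": n_tract,
                "probability": (n_tract / n_genes) if n_genes else np.nan,
                "cluster": int(smap.clusters[h - 1]) if smap.clusters is not None else 0,
            }
        )
    hex_table = pd.DataFrame(rows)
    if smap.clusters is not None:
        pooled = (
            hex_table.groupby("cluster")[["n_genes", "n_tractable"]].sum().reset_index()
        )
        pooled["percentage"] = np.where(
            pooled["n_genes"] > 0,
            100.0 * pooled["n_tractable"] / pooled["n_genes"],
            np.nan,
        )
    else:
        pooled = pd.DataFrame(columns=["cluster", "n_genes", "n_tractable", "percentage"])
    return hex_table, pooled


def disease_correlations(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between disease columns with t-test p."""
    x, genes, diseases = _profiles_matrix(profiles)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for correlation")
    m = len(diseases)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            if x[:, i].std() == 0 or x[:, j].std() == 0:
                warnings.warn(
                    f"zero-variance profile ({diseases[i]} vs {diseases[j]}); r is NA",
                    stacklevel=2,
                )
                continue
            res = pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=diseases, columns=diseases),
        pd.DataFrame(p, index=diseases, columns=diseases),
    )


def tractability_enrichment(
    subset: Iterable[str], tract: pd.DataFrame, universe: Iterable[str]
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``subset`` in tractable genes."""
    status = tract.set_index("gene")["tractable"] if "gene" in tract.columns else tract["tractable"]
    tractable = set(status.index[status.astype(bool)])
    universe = frozenset(universe)
    members = tractable & universe
    if not members:
        warnings.warn("no tractable genes in the universe", stacklevel=2)
        members = set()
    sets = GeneSetCollection([("tractable", "druggable-pocket genes", members or {"__none__"})])
    query = frozenset(subset) & universe
    uni = universe | ({"__none__"} if not members else set())
    return fisher_enrichment(query, sets, uni)
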
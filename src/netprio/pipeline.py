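"""End-to-end driver: simulate -> prioritize -> enrich -> crosstalk ->
repurpose -> robustness -> crossmap, with a deterministic JSON summary."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossdisease, crosstalk, enrichment, io, prioritize, repurpose, robustness
from .config import PipelineConfig
from .exceptions import PipelineStageError
from .synthetic import simulate

logger = logging.getLogger("netprio.pipeline")

STAGES = (
    "simulate",
    "prioritize",
    "enrich",
    "crosstalk",
    "repurpose",
    "robustness",
    "crossmap",
)


def _stage(name: str):
    def deco(fn):
        def wrapped(state, config, outdir):
            t0 = time.perf_counter()
            logger.info("stage %s: start (seed=%d)", name, config.seed)
            try:
                fn(state, config, outdir)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

        wrapped.stage_name = name
        return wrapped

    return deco


@_stage("simulate")
def _run_simulate(state, config: PipelineConfig, outdir: Path):
    dataset = simulate(config.synthetic.to_config(config.seed))
    io.write_dataset(dataset, outdir / "inputs")
    state["dataset"] = dataset
    state["summary"]["simulate"] = {
        "n_genes": dataset.network.number_of_nodes(),
        "n_edges": dataset.network.number_of_edges(),
        "module_size": len(dataset.truth.module_genes),
        "n_sets": len(dataset.genesets),
    }


@_stage("prioritize")
def _run_prioritize(state, config: PipelineConfig, outdir: Path):
    ds = state["dataset"]
    params = prioritize.RWRParams(
        restart=config.rwr.restart,
        tol=config.rwr.tol,
        max_iter=config.rwr.max_iter,
        layer_weights=config.rwr.layer_weights,
    )
    seeds = prioritize.combine_evidence(ds.evidence, params.layer_weights)
    result = prioritize.propagate(ds.network, seeds, params)
    priority = prioritize.rate(result.affinity)
    io.write_table(priority, outdir / "priority.tsv")
    state["priority"] = priority
    state["summary"]["prioritize"] = {
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "top_rating": float(priority["rating"].iloc[0]),
    }


@_stage("enrich")
def _run_enrich(state, config: PipelineConfig, outdir: Path):
    ds, priority = state["dataset"], state["priority"]
    universe = set(priority["gene"])
    query = set(
        prioritize.top_fraction(priority, config.enrichment.pathway_top_fraction)
    )
    fisher = enrichment.fisher_enrichment(query, ds.genesets, universe)
    io.write_table(fisher, outdir / "enrichment_fisher.tsv", sort_by="set_id")
    tsea = enrichment.tsea(
        priority,
        ds.genesets,
        n_perm=config.enrichment.tsea_n_perm,
        weight_exponent=config.enrichment.tsea_weight_exponent,
        rng=np.random.default_rng([config.seed, 101]),
    )
    io.write_table(tsea, outdir / "enrichment_tsea.tsv", sort_by="set_id")
    state["fisher"] = fisher
    state["summary"]["enrich"] = {
        "n_sets_tested": int(len(fisher)),
        "n_fisher_fdr_lt_0.05": int((fisher["FDR"] < 0.05).sum()),
        "n_tsea_fdr_lt_0.05": int((tsea["FDR"] < 0.05).sum()) if len(tsea) else 0,
    }


@_stage("crosstalk")
def _run_crosstalk(state, config: PipelineConfig, outdir: Path):
    ds, priority = state["dataset"], state["priority"]
    params = crosstalk.CrosstalkParams(
        theta_quantile=config.crosstalk.theta_quantile,
        n_perm=config.crosstalk.n_perm,
        degree_bin_width=config.crosstalk.degree_bin_width,
        exact_max_nodes=config.crosstalk.exact_max_nodes,
        seed=config.seed,
    )
    theta = crosstalk.theta_from_quantile(priority, params.theta_quantile)
    scores = crosstalk.score_nodes(priority, theta)
    module = crosstalk.find_crosstalk(ds.network, scores, params)
    perm = crosstalk.permutation_significance(
        ds.network, scores, module.total_score, params
    )
    module.p_perm = perm.p_empirical
    module.p_extrapolated = perm.p_extrapolated
    io.write_edge_list(module.subgraph(ds.network), outdir / "crosstalk_edges.tsv")
    nodes = priority[priority["gene"].isin(module.genes)][["gene", "rating", "rank"]]
    io.write_table(nodes, outdir / "crosstalk_nodes.tsv", sort_by="gene")
    pgraph = crosstalk.pathway_graph(
        module.genes, ds.genesets, set(priority["gene"]), config.crosstalk.pathway_fdr
    )
    io.write_table(pgraph.edges, outdir / "pathway_graph.tsv")
    state["module"] = module
    state["summary"]["crosstalk"] = {
        "theta": float(theta),
        "n_module_genes": len(module.genes),
        "total_score": float(module.total_score),
        "p_perm": float(perm.p_empirical),
        "p_extrapolated": float(perm.p_extrapolated),
        "n_significant_pathways": int(len(pgraph.nodes)),
    }


@_stage("repurpose")
def _run_repurpose(state, config: PipelineConfig, outdir: Path):
    ds, priority, module = state["dataset"], state["priority"], state["module"]
    categories = repurpose.max_phase_targets(ds.drugs)
    io.write_table(categories, outdir / "target_categories.tsv", sort_by="gene")
    enr = repurpose.category_enrichment(
        module.genes, categories, set(priority["gene"])
    )
    io.write_table(enr, outdir / "category_enrichment.tsv")
    targeted = sorted(
        set(categories.loc[categories["category"] != "none", "gene"])
        & set(module.genes)
    )
    state["drug_candidates"] = targeted
    state["summary"]["repurpose"] = {
        "n_approved": int((categories["category"] == "approved").sum()),
        "n_phased": int((categories["category"] == "phased").sum()),
        "n_candidates_in_module": len(targeted),
        "category_p": {
            row["category"]: float(row["p"]) for _, row in enr.iterrows()
        },
    }


@_stage("robustness")
def _run_robustness(state, config: PipelineConfig, outdir: Path):
    ds, module = state["dataset"], state["module"]
    graph = module.subgraph(ds.network)
    candidates = state.get("drug_candidates") or list(module.genes)
    k_max = min(config.robustness.k_max, len(candidates))
    combos = robustness.optimal_combination(
        graph,
        candidates,
        k_min=min(config.robustness.k_min, k_max),
        k_max=k_max,
        convention=config.robustness.convention,
    )
    rows = []
    for k, results in sorted(combos.items()):
        for res in results:
            rows.append(
                {
                    "k": k,
                    "removed": "|".join(res.removed),
                    "fraction_disconnected": res.fraction_disconnected,
                    "convention": res.convention,
                }
            )
    io.write_table(pd.DataFrame(rows), outdir / "optimal_removal.tsv")
    curve = robustness.targeted_attack(graph, "degree", convention=config.robustness.convention)
    io.write_table(
        pd.DataFrame(curve.points, columns=["fraction_removed", "fraction_disconnected"]),
        outdir / "attack_degree.tsv",
    )
    state["summary"]["robustness"] = {
        "best_fraction_per_k": {
            str(k): float(results[0].fraction_disconnected)
            for k, results in sorted(combos.items())
        },
        "optimal_combination": {
            str(k): list(results[0].removed) for k, results in sorted(combos.items())
        },
    }


@_stage("crossmap")
def _run_crossmap(state, config: PipelineConfig, outdir: Path):
    ds, module = state["dataset"], state["module"]
    profiles = ds.disease_profiles
    module_profiles = profiles[profiles["gene"].isin(module.genes)]
    if len(module_profiles) < config.crossmap.radius * 4:
        module_profiles = profiles  # too few module genes: map everything
    smap = crossdisease.build_map(config.crossmap.radius)
    params = crossdisease.SOMParams(
        epochs=config.crossmap.epochs,
        alpha0=config.crossmap.alpha0,
        k_clusters=config.crossmap.k_clusters,
        seed=config.seed,
    )
    trained = crossdisease.train_som(smap, module_profiles, params)
    labels = crossdisease.cluster_map(trained, config.crossmap.k_clusters)
    hex_table, cluster_table = crossdisease.overlay_binary(trained, ds.tractability)
    io.write_table(hex_table, outdir / "crossmap_overlay.tsv")
    io.write_table(cluster_table, outdir / "crossmap_clusters.tsv")
    corr, _ = crossdisease.disease_correlations(module_profiles)
    corr.to_csv(outdir / "disease_correlations.tsv", sep="\t")
    payload = {
        "radius": trained.radius,
        "coords": [list(c) for c in trained.coords],
        "codebook": trained.codebook.tolist(),
        "diseases": list(trained.diseases),
        "bmu": {g: int(h) for g, h in trained.bmu.items()},
        "clusters": [int(c) for c in labels],
    }
    (outdir / "crossmap.json").write_text(json.dumps(payload, indent=2) + "\n")
    sizes = {}
    for lab in sorted(set(labels)):
        sizes[f"C{lab}"] = int((labels == lab).sum())
    state["summary"]["crossmap"] = {
        "n_hexagons": trained.n_hex,
        "cluster_sizes": sizes,
        "final_qe": float(trained.qe_history[-1]),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; writes outputs plus ``summary.json`` and a log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        state: dict = {"summary": {"seed": config.seed}}
        for stage in (
            _run_simulate,
            _run_prioritize,
            _run_enrich,
            _run_crosstalk,
            _run_repurpose,
            _run_robustness,
            _run_crossmap,
        ):
            stage(state, config, outdir)
        summary = state["summary"]
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
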
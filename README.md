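# netprio

Genetics-led network target prioritization and its downstream analyses,
exercisable end-to-end on synthetic data with planted ground truth.

The pipeline mirrors a common systems-biology workflow for turning per-gene
genetic evidence into therapeutic hypotheses:

1. **prioritize** — combine non-negative evidence layers (`nGene`, `eGene`,
   `cGene`) into seed scores and propagate them over a gene-interaction
   network with a restart walk (`p ← (1−r)·W·p + r·p0`, column-normalized
   adjacency). Affinities map to a 0–5 priority rating (rank-based, top
   gene → 5).
2. **enrichment** — one-sided Fisher over-representation of top-rated genes
   in gene-set collections (hypergeometric upper tail, Haldane-corrected OR,
   95% CI, hypergeometric z-score, BH FDR), plus rank-based set enrichment
   with a weighted running sum, permutation-normalized NES, and extraction
   of the "leading" members ahead of the enrichment peak.
3. **crosstalk** — a maximum-scoring connected subnetwork of highly rated
   genes (exact enumeration on small graphs, Steiner-style heuristic above
   that), with significance from a degree-preserving score-permutation test
   (empirical p with pseudocount plus a clearly-labelled normal-fit
   extrapolation), and a pathway-centric graph filtered to its minimum
   spanning tree on 1/shared-gene-count distances.
4. **repurpose** — per-gene maximum clinical development phase from a
   drug-target table (phase IV → approved, I–III → phased) and Fisher
   enrichment of module genes in each category.
5. **robustness** — fraction of the network disconnected from the largest
   remaining component after node removal (both conventions for counting
   the removed nodes), exhaustive optimal drug-combination search over
   size-k removal sets, and static targeted-attack curves ordered by
   degree, betweenness, or priority.
6. **crossdisease** — a supra-hexagonal self-organizing map (19 hexagons at
   radius 3) trained on gene × disease priority profiles, partitioned into
   contiguous clusters, overlaid with binary tractability labels, and
   accompanied by pairwise disease correlations.
7. **synthetic** — generators for every input above with a planted connected
   module, enriched gene sets, module-concentrated drug targets, correlated
   disease profiles, and binary tractability labels, all byte-reproducible
   from a single seed.

## Command line

Every stage is a subcommand of `netprio`; `run` drives the whole synthetic
pipeline and writes TSV/GMT/JSON outputs plus a deterministic
`summary.json`:

```sh
netprio simulate --seed 7 --outdir out/inputs
netprio prioritize --network out/inputs/network.tsv \
    --evidence out/inputs/evidence.tsv --restart 0.75 --out out/priority.tsv
netprio enrich fisher --priority out/priority.tsv \
    --gmt out/inputs/genesets.gmt --top-fraction 0.02 --out out/fisher.tsv
netprio crosstalk --network out/inputs/network.tsv --priority out/priority.tsv \
    --theta-quantile 0.95 --nperm 100 --seed 7 --outdir out/crosstalk
netprio robustness combo --network out/crosstalk/crosstalk_edges.tsv \
    --k-max 3 --out out/combos.tsv
netprio crossmap --profiles out/inputs/disease_profiles.tsv \
    --tract out/inputs/tractability.tsv --radius 3 --k 4 --seed 7 --outdir out/map
netprio run --config configs/default.yaml --outdir out/full
```

## Formats

TSV everywhere (UTF-8, '.' decimal, empty field = NA), GMT for gene sets,
JSON for the planted truth, map export, and run summaries, YAML for the
strictly validated pipeline configuration (`configs/default.yaml`). Gene
identity is the case-sensitive symbol string; no alias resolution is
attempted.
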
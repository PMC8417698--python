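# Default end-to-end pipeline configuration (all values overridable).
version: 1
seed: 0
synthetic:
  n_genes: 500
  network_model: preferential_attachment
  mean_degree: 4.0
  module_size: 20
  evidence_effect: 3.0
  noise_sd: 1.0
  n_sets: 50
  set_size_range: [10, 40]
  n_enriched_sets: 5
  n_diseases: 6
  shared_signal_fraction: 0.5
  tractable_rate: 0.3
rwr:
  restart: 0.75
  tol: 1.0e-10
  max_iter: 10000
  layer_weights: null
enrichment:
  pathway_top_fraction: 0.02
  neighbor_top_fraction: 0.01
  tsea_n_perm: 200
  tsea_weight_exponent: 1.0
crosstalk:
  theta_quantile: 0.95
  n_perm: 100
  degree_bin_width: 1
  exact_max_nodes: 15
  pathway_fdr: 0.05
robustness:
  convention: exclude_removed
  k_min: 1
  k_max: 3
crossmap:
  radius: 3
  k_clusters: 4
  epochs: 60
  alpha0: 0.5
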
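# Small synthetic cohort used by tests and examples: 200 enzymes with
# a planted PTM-enriched group (multiplier 3).
synthetic:
  n_enzymes: 200
  enrichment_multiplier: 3.0
predominant_threshold: 0.60
sensitivity_thresholds: [0.50, 0.60, 0.70]
hotspot_half_window: 7
hotspot_min_neighbors: 5
crosstalk_mode: residue
sparsity_threshold: 0.01
k_min: 2
k_max: 10
cluster_method: agglomerative_ward
q_threshold: 0.05
seed: 0
out_dir: ptmatlas_run_small
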
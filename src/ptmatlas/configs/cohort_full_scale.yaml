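# Cohort at the scale of a full human metabolic-enzyme catalog:
# 771 enzymes, planted enriched group at multiplier 3.
synthetic:
  n_enzymes: 771
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
out_dir: ptmatlas_run_full_scale
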
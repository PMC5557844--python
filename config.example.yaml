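# Full-pipeline run on synthetic data; every key is optional and
# falls back to the defaults shown in stressdiel.pipeline.DEFAULT_CONFIG.
out_dir: results/run
seed: 1
simulate:
  enabled: true
  n_genes: 1000
  n_series: 9
  replicates_per_series: 3
  frac_up: 0.1
  frac_down: 0.1
  effect_size: 2.0
  frac_rhythmic: 0.5
  amplitude: 1.0
  noise_sd: 0.25
  annotations: {n_terms: 50, planted_term_fold: 10.0}
  interactions: {n_pathway_genes: 11, n_partners: 69}
drought:
  k: 10
  up_threshold: 1.0
  down_threshold: 1.0
diurnal:
  k: 7
  r2_threshold: 0.3
enrichment:
  min_fold: 2.0
  alpha: 0.05
network:
  pcc_threshold: 0.5
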
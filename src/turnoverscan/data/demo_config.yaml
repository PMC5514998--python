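# Demo pipeline run on synthetic data (small, seconds to complete).
out_dir: demo_out
seed: 11
simulate:
  n_tissues: 12
  n_genes: 300
  frac_signal: 0.1
  slope_range: [0.5, 1.0]
  model: BM
  sigma2: 0.25
  baseline_mean: 6.0
  n_replicates: 3
  replicate_noise_sd: 0.1
  seed: 11
pre_normalized: true
qc_threshold: 0.9
tree_method: pearson
n_boot: 50
scan:
  q_threshold: 0.05
  models: [BM, LAMBDA, OU]
groups:
  first_clade: [T01, T02]
n_sim: 199
p_threshold: 0.01
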
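# Full-pipeline config for `tdufe run-all`. Every key shown with its default
# unless noted; omitted keys fall back to documented defaults (see RunConfig).
input_mode: synthetic
synthetic:
  n_features: 10000
  n_replicates: 8
  n_slices: 2
  n_signal: 500
  effect_size: 6.0
  noise_sd: 1.0
  count_model: gaussian
normalization_policy: per_column
log_offset: null
min_nonzero: 0
min_variance: 0.0
# manual factor overrides (null = automatic criteria)
l1: null
l2: null
l3: null
groups: null            # e.g. "A101D:MeWo" for named slice partitions
threshold: 0.01         # BH-adjusted p cutoff
n_bins: 100
exclude_low_p_bins: 1
gmt_paths: []           # enrichment skipped when empty
min_overlap: 1
seed: 1
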
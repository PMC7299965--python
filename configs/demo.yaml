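# Demo pipeline configuration: small synthetic cohort, full analysis.
seed: 1
synthetic:
  n_per_group: 6
  n_normal: 6
  n_genes: 500
  n_cpgs: 1500
  n_window_cpgs: 200
  n_meth_genes: 40
  n_diff_genes: 8
compare:
  features: [purity, gii, proliferation, emt, window_mean_z]
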
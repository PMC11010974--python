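# Small-cohort configuration for quick end-to-end runs.
cohort:
  n_cr: 3
  n_ad: 3
  cells_per_patient: [500, 900]
  doublet_fraction: 0.05
  dead_fraction: 0.05
pregate:
  cell_cap: 120
embed:
  perplexity: 20
  n_iter: 300
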
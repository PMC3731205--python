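# Demo run configuration for `sumoquant run-all --config examples/run_config.yaml`
generator:
  seed: 7
  n_proteins: 120
  target_fraction: 0.5
  contaminant_fraction: 0.35
  peptide_noise_sigma: 0.2
  missing_channel_prob: 0.05
params:
  noise_floor: 1000.0
  min_unique_peptides: 3
  fold_cutoff: 10.0
designs: default
output_dir: sumoquant_out
log_level: INFO
include_gcr: true
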
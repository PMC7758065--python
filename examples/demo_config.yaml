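# Demo: simulated two-population tissue, intrinsic-transcription scenario.
# Run:  ambint run --config examples/demo_config.yaml --out-dir out/
seed: 1
scenario: intrinsic

simulate:
  n_parenchyma: 200
  n_target: 500
  n_genes: 2000
  depth: 100000
  reads_per_group: 6000
  contamination_fraction: 0.02   # used only by the contamination/mixed scenarios
  burst_probability: 0.08

markers:
  min_frac: 0.60
  min_fold: 10.0
  n: 15

thresholds:
  tau_max: 0.3
  k_max: 2
  open_frac_min: 0.5
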
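# Desk-scale example run: 12 HC + 12 pwRRMS at 24 x 24 x 40 voxels (0.5 mm),
# default group effects (WM FA -0.02, GM FA -0.04) and lesion model.
# Run with:  cordlevel run --config configs/example.yaml
seed: 7
output_dir: scratch/example_run
cohort:
  n_hc: 12
  n_ms: 12
acquisition:
  n_directions: 15
  b_value: 750
  n_averages: 3
  snr: 20
levels:
  min_voxels: 1
stats:
  alpha_group: 0.05
  alpha_level: 0.01
  alpha_fdr: 0.05
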
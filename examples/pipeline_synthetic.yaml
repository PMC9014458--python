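# Full synthetic pipeline: sample -> cluster -> weight -> sites.
# Run:  microsolv all --config examples/pipeline_synthetic.yaml --outdir out
mode: synthetic
seed: 5
temperature: 298.15
cluster_cutoff: 1.0
population_threshold: 0.01
hbond_d_max: 3.5
hbond_angle_min: 120.0   # relaxed for the librating toy water, see docs/methods.md
output_dir: microsolv_out
toy:
  n_waters: 2
  mc_steps: 8000
  stride: 60
  equilibration: 1000
observable:
  vde0: 1.30
  site_increments: {AMINE_N10: 0.50, PHOSPHATE: 0.30}
  noise_sd: 0.0
  relaxation_offset: 0.35
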
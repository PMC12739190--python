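# Full-study run configuration: 10,000 calibrated profiles, 2,000-profile
# scenario presets, ±20% sensitivity, convergence grid 1,000..12,000.
# Run with:  ddrs run-all --config examples/study_config.yaml
generator:
  n_profiles: 10000
  seed: 42
  latent_shape_a: 2.0
  latent_shape_b: 2.0
  noise_alpha: {S: 2.0, A: 2.0, K: 2.0, Q: 2.0}
  noise_beta: {S: 3.0, A: 3.0, K: 3.0, Q: 3.0}
  lambda_S: 0.66
  lambda_A: 0.57
  lambda_K: 0.73
  lambda_Q: 0.50
  lambda_M: 0.49
  sigma_dpi: 16.8
  sigma_hei: 15.8
weights:
  w_S: 0.40
  w_A: 0.20
  w_K: 0.25
  w_Q: 0.15
scenario_spec:
  healthy_min: 70.0
  unhealthy_max: 30.0
sensitivity_pct: 0.20
convergence_grid: [1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000, 9000, 10000, 11000, 12000]
scenario_n: 2000
output_dir: study_out
seed: 42
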
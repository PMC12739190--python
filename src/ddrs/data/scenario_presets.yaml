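# Frozen scenario presets (fixture version 1).
#
# Each preset is the calibrated base generator with the latent diet-quality
# factor re-shaped (and noise shapes / MEDAS coupling adjusted) so the
# cohort matches its dietary scenario: index means >= 70 (healthy),
# <= 30 (unhealthy), or near (MEDAS 55, DPI 25, HEI 65) for mixed diets
# that are moderate overall but poor in phytochemical-rich foods
# (the mixed preset decouples protective-food intake from the latent
# factor: lambda_K = 0 with a low-mean noise beta).
healthy:
  n_profiles: 2000
  seed: 42
  latent_shape_a: 7.0
  latent_shape_b: 1.0
  noise_alpha: {S: 5.0, A: 5.0, K: 2.0, Q: 5.0}
  noise_beta: {S: 3.0, A: 3.0, K: 4.0, Q: 3.0}
  lambda_S: 0.66
  lambda_A: 0.57
  lambda_K: 0.73
  lambda_Q: 0.50
  lambda_M: 0.70
  sigma_dpi: 5.0
  sigma_hei: 5.0
unhealthy:
  n_profiles: 2000
  seed: 42
  latent_shape_a: 1.5
  latent_shape_b: 17.0
  noise_alpha: {S: 2.0, A: 2.0, K: 2.0, Q: 2.0}
  noise_beta: {S: 3.0, A: 3.0, K: 3.0, Q: 3.0}
  lambda_S: 0.66
  lambda_A: 0.57
  lambda_K: 0.73
  lambda_Q: 0.50
  lambda_M: 0.65
  sigma_dpi: 5.0
  sigma_hei: 5.0
mixed:
  n_profiles: 2000
  seed: 42
  latent_shape_a: 3.5
  latent_shape_b: 1.5
  noise_alpha: {S: 5.0, A: 5.0, K: 2.0, Q: 3.0}
  noise_beta: {S: 3.0, A: 3.0, K: 6.0, Q: 3.0}
  lambda_S: 0.66
  lambda_A: 0.57
  lambda_K: 0.0
  lambda_Q: 0.80
  lambda_M: 0.25
  sigma_dpi: 5.0
  sigma_hei: 5.0
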
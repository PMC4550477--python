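# Reconstruction config for a 10 x 10, 0.4 mm-pitch array.
# Tissue values are placeholders of plausible magnitude - replace with
# layer-resolved literature values for your preparation.
grid: {nx: 10, ny: 10, pitch_mm: 0.4}
layers:
  - {x_from_mm: 0.0, x_to_mm: 1.2, sigma_S_per_m: 0.25, eps_rel: 1.0e5, mu_rel: 1.0}
  - {x_from_mm: 1.2, x_to_mm: 2.4, sigma_S_per_m: 0.35, eps_rel: 1.0e5, mu_rel: 1.0}
  - {x_from_mm: 2.4, x_to_mm: 3.6, sigma_S_per_m: 0.30, eps_rel: 1.0e5, mu_rel: 1.0}
anisotropy_ratio: 1.0
reconstruction:
  z_mm: 0.15
  kc_frac_nyquist: 0.8
  alpha: 0.1
  pad_factor: 1
  upsample_factor: 3
superresolution:
  factor: 3
  max_iter: 500
  tol: 1.0e-8
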
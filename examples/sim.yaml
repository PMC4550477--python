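# Forward-simulation config: two buried disc sources under the array.
grid: {nx: 10, ny: 10, pitch_mm: 0.4}
layers:
  - {x_from_mm: 0.0, x_to_mm: 3.6, sigma_S_per_m: 0.3, eps_rel: 1.0e5, mu_rel: 1.0}
sources:
  - shape: disc
    centre_mm: [0.8, 0.8]
    depth_mm: 0.1
    radius_mm: 0.3
    amplitude: 1.0
    sinusoids: [{freq_hz: 1.5, phase_rad: 0.0}]
  - shape: disc
    centre_mm: [2.8, 2.8]
    depth_mm: 0.2
    radius_mm: 0.6
    amplitude: 1.0
    sinusoids: [{freq_hz: 1.5, phase_rad: 1.0472}]
duration_s: 20.0
sample_rate_hz: 200.0
noise_frac: 0.1
seed: 1234
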
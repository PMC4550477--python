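# neholo — near-field electromagnetic holography for microelectrode arrays

`neholo` reconstructs spatial maps of electromagnetic energy flow inside
neural tissue from voltages recorded on a planar microelectrode array
(e.g. a 10 × 10 Utah-style grid at 0.4 mm pitch lying on a neocortical
slice).  It is aimed at electrophysiologists who want more than a current
source density map from slow cortical rhythms: where activity sources
sit, where their energy goes, and how much is dissipated locally.

## The method

A recorded potential map `P` on the array is treated as a hologram of
the buried sources.  Per temporal frequency ω the pipeline computes, at a
chosen reconstruction depth `z` inside the tissue:

- electric field at the array: `E = ∇P` (central differences);
- back-propagation through k-space: `E_z = F⁻¹(F E · G_z · K_filter)`
  with the angular-spectrum propagator `G_z = e^{−i k_z z}`,
  `k_z = √(k² − k_x² − k_y²)` on the decaying branch, and a smooth
  low-pass filter `K_filter(k_r; k_c, α)` that controls the
  resolution/noise trade-off;
- the characteristic wavenumber `k = ω√(μ ε̂)` uses the lossy
  permittivity `ε̂ = ε + iσ/ω` of the layered tissue model (conductivity
  σ, permittivity ε, permeability μ per cortical-depth band);
- the normal field component, inferred from the source-free Laplace
  continuation `Ê_z = −(k_x Ê_x + k_y Ê_y)/k_z`;
- magnetic-field estimate `H_z = F⁻¹(K × F E)` with `K = (k_x, k_y, k_z)`,
  applied to the measured in-plane field;
- Poynting energy flow `S_z = E_z × H_z`, its divergence — the **energy
  source density** (ESD, the electromagnetic analogue of CSD) — and the
  ohmic dissipation `D_z = σ|E_z|²`.

Virtual electrodes are inserted between real ones by Papoulis–Gerchberg
band-limited interpolation (×3 by default) before reconstruction.  All
reconstructed magnitudes are in arbitrary units; spatial structure,
phase and flow direction are the meaningful outputs.

A forward simulator (oscillating disc/point sources at known depth,
projected to the array with the same angular-spectrum decay, plus seeded
noise) provides ground truth, and a wavelet phase-semblance module
quantifies how well reconstructed time series match the originals.

## Worked example

```python
import numpy as np
import neholo as nh
from neholo.metrics import find_peaks_2d

rec = nh.simulate_recording(nh.fig1b_like(seed=1))   # two buried discs, 10% noise
phasor = nh.temporal_phasor(rec.voltage, rec.sample_rate_hz, 1.5)
result = nh.reconstruct(nh.ScalarFieldFrame(phasor, rec.geometry), rec.medium,
                        nh.ReconstructionParams(z_mm=0.15))

esd = np.abs(result.esd.values)
pitch = result.esd.geometry.pitch_eff
for iy, ix, v in find_peaks_2d(esd, rel_threshold=0.5, min_distance=2):
    print(f"ESD peak at x={ix*pitch:.2f} mm, y={iy*pitch:.2f} mm (value {v:.3g} a.u.)")

pairs = nh.superresolution_experiment(rec)           # 5x5 -> 10x10 comparison
test = nh.paired_compare(pairs)
print(f"median semblance: interpolation {pairs.semblance_interp.median():.3f}, "
      f"holography {pairs.semblance_neh.median():.3f} (Wilcoxon p = {test.p_value:.2g})")
```

prints

```
ESD peak at x=0.80 mm, y=0.80 mm (value 14.1 a.u.)
ESD peak at x=2.80 mm, y=2.80 mm (value 13.6 a.u.)
median semblance: interpolation 0.514, holography 0.553 (Wilcoxon p = 0.00048)
```

The two ESD peaks land exactly on the true source centres (0.8, 0.8) and
(2.8, 2.8) mm — sub-electrode localisation from a 0.4 mm-pitch array —
and the holographically reconstructed time series track the original
recording significantly better than plain band-limited interpolation of
the spatially downsampled data.

## Command line

```sh
neholo fixtures  --name fig1b_like --out demo/
neholo reconstruct --config cfg.yaml --input demo/fig1b_like.h5 --out out.h5 --png-dir demo/png
neholo regions   --config cfg.yaml --input demo/fig1b_like.h5 --regions regions.yaml --csv vectors.csv
neholo validate  --input demo/fig1b_like.h5 --out report.json --csv pairs.csv
```

See `neholo.io` for the YAML config schema (grid, tissue layers,
reconstruction parameters) and the HDF5 recording layout.

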
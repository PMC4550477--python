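# Methods

## Model and assumptions

The package treats a planar microelectrode recording as a boundary
measurement of a quasi-static electromagnetic field generated by sources
inside the tissue.  Coordinates: `x` runs along cortical depth within the
recording plane (column 0 at the pia), `y` along the layers, `z` is the
normal pointing from the array into the slice.  Arrays are `(ny, nx)`;
units are mm, rad/mm, rad/s and S/m.

Key physical assumptions:

- **Quasi-stationarity.** Slow rhythms (0.5–4 Hz) are processed at a
  single representative temporal frequency ω; the spatial operators are
  time-invariant, so voltage movies stream through the same k-space
  multipliers frame by frame.
- **Homogeneous propagation plane.** The k-space propagator assumes one
  (σ, ε, μ) per plane; the layered medium enters the propagator through
  the spatial mean of its per-node maps, while the per-node σ map is used
  in the dissipation formula.  A full per-node treatment is impossible
  for a diagonal k-space operator and is out of scope.
- **Source-free gap.** Back-propagation is exact only if no sources sit
  between the array and the reconstruction plane.  In tissue this is
  never strictly true; reconstructions are therefore estimates that
  favour the strongest, most spatially compact sources, and a
  reconstruction plane behaves like a local depth average, not a sharp
  focal plane.
- **Quasi-static wavenumbers.** At ω ≈ 2π·1.5 rad/s with σ ≈ 0.3 S/m the
  characteristic wavenumber magnitude is ~1e−6 rad/mm against a grid
  Nyquist of 7.85 rad/mm: every non-DC lattice mode is evanescent and
  the propagator is essentially the decay `exp(−k_r z)`.  Depth
  separation of structure therefore comes from differential smoothing,
  not from interference focusing.

## The operator chain and the normal-component closure

The printed chain E = ∇P, H = K × FE, S = E × H has a degeneracy that an
implementation must confront: a gradient field is curl-free, so with the
normal component set to zero, K × FE vanishes analytically and the
in-plane Poynting components consist entirely of finite-difference
residue (lattice-anisotropic, O(h²)).  The resulting ESD map is a
quadrupole artifact with a null at each source centre.

The package therefore closes the system physically:

- the **normal electric component** is inferred from the source-free
  continuation of the potential below the plane
  (`Ê_z = −(k_x Ê_x + k_y Ê_y)/k_z`, i.e. ∂P/∂z of the harmonic
  continuation toward the sources);
- the **magnetic estimate** `H = K × FE` uses the measured in-plane
  components only.  (Using the inferred normal component there would make
  Ê ∥ K mode-by-mode and annihilate H — the plane-wave statement "a field
  polarised along its wavevector has no magnetic partner".)

With this closure the dominant in-plane energy flow is
`S_∥ ∝ −E_z · k_z · E_∥`: the normal field times the azimuthal magnetic
estimate, a radial source-centred pattern, so `div S` peaks on buried
sources — the behaviour the method's maps display.  The sign convention
of `E = +∇P` and numpy's FFT kernel (which maps `k → −k` relative to the
`e^{+ik·x}` analysis convention) can flip the sign of H and hence of S
and ESD; since all magnitudes are arbitrary units, maps are analysed as
magnitudes or with explicitly declared sign conventions.  The literal
`E_z = 0` closure remains available (`normal_closure="zero"`).

The unconjugated product `S = E × H` is the default; with near-real
phasors and `k_z ≈ −i k_r`, S is then predominantly imaginary — the
reactive (resonant) near-field component — consistent with splitting the
complex flow into a real "propagating" and imaginary "resonant" part.
The conjugated physics convention `E × conj(H)` sits behind
`poynting_conjugate=True`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `z_mm` | 0.1 | reconstruction depth; useful range ≈ 0.065–0.265 mm for 0.4 mm pitch |
| `kc` | 0.8 × π/pitch | filter cutoff, rad/mm |
| `alpha` | 0.1 | filter roll-off steepness (dimensionless) |
| `upsample_factor` | 3 | Papoulis–Gerchberg virtual-electrode factor |
| `pad_factor` | 1 | zero-padding per axis in `propagate` |
| `omega` | 2π·1.5 | representative temporal frequency, rad/s |
| σ, ε_r, μ_r | 0.3 S/m, 1e5, 1 | placeholder tissue values, configurable per layer |

Filter defaults were fixed once with the package's own focusing
diagnostic on the built-in two-source fixture: sweep `kc` and `z`,
maximise the joint dominance of the known source peaks over the map
background.  `kc = 0.8 ×` Nyquist keeps most of the measured band while
taper­ing the noisiest octave; α = 0.1 makes the transition sharp enough
that the cutoff is meaningful.  The filter/plane-distance matching is
heuristic by nature — the package exposes both knobs and the diagnostic
(`neholo.metrics.two_peak_contrast`).

The tissue property defaults are clearly-labelled placeholders of
plausible magnitude, not literature ground truth; layered values belong
in the YAML config.  The across/along-layer anisotropy ratio enters only
as a scalar rescaling of σ in the wavenumber and dissipation — no claim
of tensor fidelity is made.

### Zero-padding

`propagate` supports mean-removal + zero-padding to fight spectral
leakage of non-periodic frames.  The reconstruction default is
`pad_factor = 1`: after Papoulis–Gerchberg interpolation a frame is
already periodic and band-limited, and padding such a frame would
*reintroduce* a boundary step (empirically this pushes all ESD energy to
the grid edges).  The forward simulator, whose source frames are
compactly supported, pads by 2.

### Papoulis–Gerchberg interpolation

Alternating projections between "agrees with the measured samples" and
"band-limited to the raw-grid Nyquist" (the information ceiling; the
band is configurable).  The iteration is initialised with the
band-limited projection of the gain-compensated zero-filled frame, which
is already exact for strictly in-band signals; measured nodes are
re-imposed after the final pass, so interpolation never alters known
samples.  Convergence: relative L2 change < 1e−8 or 500 iterations
(non-convergence sets a flag and warns rather than raising).  The sample
residual is non-increasing per iteration — asserted in tests.

### kz branch and stability

`k_z` is the principal square root of `k² − k_x² − k_y²` reflected into
the closed lower half-plane (Im ≤ 0).  In the lossless limit this equals
the real far-field branch and the `−i√(k_r²−k²)` near-field branch, and
it guarantees `|G_z| ≤ 1` for every mode and z ≥ 0 — propagation (and
back-projection, which reuses the same decaying propagator) can never
amplify.  Evanescent content in the reconstruction is controlled by the
filter, not by exponential amplification; consequently there is no
depth-inversion "refocusing", and depth selectivity arises from the
interplay of filter width, differential smoothing and the noise floor.

## The forward simulator

`simulate_recording` rasterises disc/point/rectangle sources on a grid 3×
finer than the array, projects each depth once through the decaying
propagator (all-pass filter, pad 2), expands in time as an outer product
with each source's sum-of-sinusoids analytic signal, samples the
electrode nodes and adds seeded white Gaussian noise (default sd = 10% of
the peak noiseless amplitude).  `fig1b_like` buries two discs (radii 0.3
and 0.6 mm at depths 0.1 and 0.2 mm, centres (0.8, 0.8) and (2.8, 2.8)
mm, both at 1.5 Hz with a π/3 phase offset) under the standard 10 × 10
array for 20 s at 200 Hz; `fig5_like` adds an amplitude-modulated 8 Hz
component nested in the delta cycle.

The simulator and the reconstructor share the audited propagator module
on purpose — a self-consistent setup.  What protects against circular
validation is that the propagator itself is checked against the
closed-form single-mode factor `exp(−i k_z z)`, and the interpolator
against analytic band-limited fields; the end-to-end tests then check
*method* properties (localisation, focusing, noise behaviour), not
physics fidelity.  Passing tests therefore show internal correctness and
the method's behaviour under its own assumptions; they do not show that
real tissue satisfies those assumptions (real recordings add correlated
noise, non-layered heterogeneity, electrode artifacts and drift that the
generator does not emulate).

## Validation experiment

The semblance comparison downsample­s the recording to every other
electrode (5 × 5), rebuilds the 10 × 10 grid by (a) Papoulis–Gerchberg
interpolation alone and (b) interpolation followed by the holographic
chain, and compares both against the original per electrode by the mean
cosine of the wavelet cross-spectrum phase over 0.5–2 Hz (complex Morlet,
5 cycles, cone-of-influence excluded, per-series standardisation).  The
stand-in series for branch (b) is the back-propagated, k-space-filtered
potential — the reconstructed quantity commensurate with a voltage
waveform; gradient components are sign-ambiguous per electrode relative
to the voltage and would corrupt a phase metric.  Branch differences are
tested with a two-sided Wilcoxon signed-rank test (paired t available).
The mechanism behind the holography branch's advantage under noise is
spatial: the propagator+filter suppress the high-spatial-frequency noise
that plain interpolation faithfully reproduces.

## Diagnostics

- **Peak finding**: local maxima above half of the map maximum
  (`maximum_filter`, plateau-safe).
- **Two-peak contrast**: min(value at the two known peak nodes) /
  max(map outside a 4-pixel disc around each) — drops when a blob fades,
  when blobs blur together, or when a too-sharp reconstruction fractures.
- **Blob width**: FWHM of the angularly averaged radial profile with
  linear interpolation of the half-max crossing.
- **SNR**: peak over background RMS outside the peak neighbourhood.

## Numerical choices and degenerate inputs

- Gradients/divergences by `np.gradient` (central differences, one-sided
  at edges); grids smaller than 3 × 3 are rejected.
- The DC term bypasses the propagator (mean removal before padding, mean
  restored after cropping) — padding stays unbiased and the identity
  `propagate(z=0) = id` is exact.
- ω = 0 is rejected (no finite loss tangent); `kc, α ≤ 0` rejected;
  filter evaluation clamps the exponent to avoid overflow at extreme
  parameters.
- Cycle averaging resamples each marked cycle to 8 phase points by linear
  interpolation; markers come from negative-going zero crossings of the
  band-passed (0.5–2 Hz Butterworth, zero-phase) grid-mean potential.
- Simulation refuses more than 200 000 time samples (desk-scale guard).
- Problem sizes in the test-suite/acceptance runs: 10 × 10 or 12 × 12
  grids, 20 s at 200 Hz, 20 repeated experiment runs — the sizes at which
  the statistical checks stabilise while a full run stays in the
  minutes range on one CPU.

## Known limitations

- Not tomographic: one plane at a time, in-plane divergence only (2
  terms); no volumetric or multi-plane joint reconstruction.
- No exact inverse (Tikhonov/deconvolution) back-propagation and no
  compressed-sensing variant.
- Regular complete grids only; no missing-electrode handling.
- Single (σ, ε) per band per run — no dispersion curves.
- Absolute magnitudes are not physical; only structure, phase and
  direction are interpretable.
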
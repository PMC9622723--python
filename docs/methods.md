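# Methods

`brimphase` converts a single off-axis hologram plus a single Brillouin
spectrum of a spherical cell into fifteen biophysical parameters. This
note documents the models implemented, the defaults and why they were
chosen, what the synthetic forward models do and do not emulate, and the
numerical choices a maintainer would want to know about.

## Physical model

**Quantitative phase imaging (QPI).** A cell imaged shortly after plating
is treated as a sphere of uniform refractive index `n̄_cell` immersed in
medium of index `n_medium`. The optical phase delay is

    φ(x, y) = (2π/λ_Q) · Δn · h(x, y),      h(x, y) = 2·√(R² − r²),

with `Δn = n̄_cell − n_medium` and `h` the projected chord length of the
sphere. Fixing the geometry from a circle fit decouples thickness from
refractive index, so the phase image yields `Δn(x, y)` directly.

**Dry mass and the two-component mixture.** The integrated phase gives
the mass of non-aqueous material through the refractive-index increment
`α ≈ 0.2 mL/g` (nearly composition independent for biomolecules):

    m_dry = (λ_Q / 2πα) ∬ φ dA.

The cell is then decomposed into a protein-like dry compartment
(`ρ_dry = 1.37 pg/µm³`) and a water-like fluid compartment
(`ρ_fluid = 1.0 pg/µm³`): `V_dry = m_dry/ρ_dry`,
`V_fluid = V_cell − V_dry`, `m_fluid = ρ_fluid·V_fluid`,
`ρ = (m_dry + m_fluid)/V_cell`, with water fractions by volume
(`θ = V_fluid/V_cell`) and by mass (`u = m_fluid/(m_fluid + m_dry)`).
Internally all arithmetic runs in a µm/pg/GHz/nm unit set in which
1 mL/g = 1 µm³/pg exactly; conversions live in `constants.py` and are
exercised by tests.

**Brillouin viscoelasticity.** Spontaneous Brillouin scattering probes
GHz-frequency longitudinal acoustics. With the density and refractive
index measured by QPI (rather than assumed),

    M′  = ρ (ν_B λ_B / 2n̄)²          storage modulus
    M″  = ρ Γ_B ν_B (λ_B / 2n̄)²      loss modulus
    η   = M″ / (2π ν_B)              longitudinal viscosity
    tanφ = M″ / M′                   loss tangent.

The identities `tanφ·M′ = M″` and `2π·ν_B·η = M″` hold to machine
precision by construction and are asserted on every processed cell.

## Processing chain and defaults

**Demodulation.** 2-D FFT; the strongest off-DC peak in the positive-
column half-plane is the carrier (a hint can override). A square window
of half-width `crop_frac·N` (default 0.175) around the carrier is
apodized with a Tukey window (cosine fraction 0.5), recentered and
inverse-transformed. The taper matters: a hard crop leaves Gibbs ringing
of ~10⁻² rad around the cell rim; with the taper the round-trip phase
error away from the boundary is ~2·10⁻⁴ rad RMS. The window size was set
as large as the default carrier geometry allows while keeping the window
clear of the DC autocorrelation halo; at the simulator's default carrier
(90, 90 cycles per 512-px field, ≈ half the Nyquist radius) a 1/8-width
window also works but roughly doubles the residual bias in `n̄` and `D`.

**Unwrapping.** The contract is modular congruence: output ≡ input
(mod 2π) at every pixel, residue-safe. `skimage.restoration.unwrap_phase`
(reliability-ordered unwrapping) satisfies it and is used directly; a
residue count is computed beforehand and flagged on the result.

**Segmentation.** Threshold at one half of the Otsu level, keep the
connected component with the largest integrated phase, close and
fill holes. Plain Otsu splits background from the bright cell core and
clips the low-phase rim of the spherical profile (mask IoU ≈ 0.87
against the true disc); halving the level recovers the rim (IoU ≥ 0.95)
while staying above the noise floor. An externally supplied mask file
overrides automatic segmentation.

**Background removal.** Least-squares 2-D polynomial (total degree ≤ 2
by default) fitted on non-cell pixels (the mask is dilated by 5 px first
so rim tails do not leak into the fit) and subtracted everywhere. The
operation is a projection and therefore idempotent.

**Sphere fit and diameter calibration.** The cell outline is the contour
where the phase crosses 5% of its maximum — the apparent boundary of the
cell in the phase image. A circular Hough transform over integer radii
(default range 4–10 µm) supplies a robust initial circle and a
confidence score; sub-pixel center and radius come from an algebraic
least-squares circle through the marching-squares contour points near
the Hough circle. The raw diameter is divided by a fixed calibration
factor (default 1.08), the bias measured on microsphere size standards:
point-spread-function blur pushes the low-level contour *outward*, and
on simulated 10 µm beads with the default PSF blur (Gaussian σ = 0.45 µm)
the raw overestimate is ≈ 8%, matching the bead calibration this divisor
encodes. Two known residuals are documented rather than hidden: (i) the
outward shift is approximately constant in absolute terms, so cells
larger than the calibration beads retain a small negative calibrated
bias (≈ −2% at 13 µm); (ii) the band-limit of the demodulation window
adds its own ≈ +0.5% outward shift for blur-free inputs, absorbed by the
bead calibration in practice. A gradient-ridge edge detector was
deliberately not used: blur moves the maximum-gradient circle *inward*,
which cannot reproduce the outward bias the calibration corrects.

**Mean refractive index.** `Δn` is averaged over `r ≤ 0.9·R` (a band of
width R/10 inside the fitted boundary is excluded against edge
artifacts) and `n_medium` (default 1.335) is added.

**Dry-mass domain.** The integral runs over the segmentation mask
dilated by 12 px — the equivalent of a generous manual crop. The
threshold mask alone clips the low-phase rim and loses ~1–5% of the
integrated phase; after background removal the extra pixels contribute
only their ≈0 residual, so the dilation is cheap and unbiased. A
`dry_mass_domain="disc"` option integrates over the fitted circle
instead.

**Brillouin spectral analysis.** Peaks are located with a prominence
threshold (2% of the dynamic range); the most prominent peak is the
elastic line (frequency origin), the strongest peaks below/above it are
Stokes/anti-Stokes. Each peak is fitted independently by least squares
with `L(f) = A(Γ/2)²/((f−c)² + (Γ/2)²) + offset + slope·(f−f₀)` over a
window of 3× its detected width; the linear term absorbs the sloping
tail of the much brighter elastic line (without it the fitted centers
shift by ~1 MHz). The shift is half the Stokes/anti-Stokes center
distance; the linewidth is the mean of the two fitted FWHMs minus the
instrument response (0.398 GHz), a linear correction mirrored exactly by
the simulator's linear broadening. Pixel→GHz dispersion comes from ≥2
elastic-order anchor pixels one FSR (29.95 GHz) apart: quadratic when 3+
anchors are available, linear for 2.

**SNR definition.** `10·log₁₀(Ā_Brillouin / σ_noise)` where `Ā` is the
mean fitted Stokes/anti-Stokes amplitude and `σ_noise` is estimated from
first differences (`std(Δcounts)/√2`) in the region beyond the outermost
peak ±3 FWHM — the differencing cancels smooth Lorentzian tails that
would otherwise masquerade as noise. Noise-free spectra are capped at
100 dB. This definition is fixed here because no single standard exists.

**Cohort statistics.** Sample mean ± SD (ddof = 1) per condition;
two-tailed Welch t-tests with Welch–Satterthwaite degrees of freedom;
Kolmogorov–Smirnov normality per group (standardized sample against the
standard normal); ordinary least-squares lines with R² and a 95%
confidence band per group and pooled. No multiple-testing correction is
applied — raw per-parameter p-values are reported, deliberately.

## Synthetic forward models

The simulators generate exactly the signal models the analysis inverts,
plus controlled imperfections:

- **Holograms**: spherical-cap phase, optional Gaussian PSF blur
  (default σ = 4.5 px = 0.45 µm, calibrated so the boundary fit
  overestimates 10 µm beads by ≈8%), a 2-D polynomial phase background
  (sub-radian tilt + twist by default), unit-visibility fringes at a
  diagonal carrier (90, 90) cycles/field, additive Gaussian intensity
  noise (default 1% of the fringe amplitude), quantization to 16 bits
  with a saturation check, and a generation-time check that the carrier
  exceeds 3× the object bandwidth.
- **Spectra**: elastic Lorentzian at 0 GHz (FWHM = instrument response)
  plus a Stokes/anti-Stokes pair at ±ν_B with FWHM = Γ_true + δν (linear
  broadening, self-consistent with the linear correction), on a 512-px
  linear dispersion axis spanning one 29.95 GHz FSR; Poisson noise over
  a 25-count baseline with amplitudes set for ≈32 dB SNR by the
  definition above.
- **Cohorts**: per-cell parameters drawn from independent normals
  truncated by resampling to physical ranges; the three default
  conditions are control (N=21), nocodazole (N=25) and hypoosmotic shock
  (N=26) with the corresponding published population means/SDs for
  diameter, refractive index, shift and linewidth. All simulators are
  pure functions of (spec, config, seed).

Not emulated: physical diffraction/speckle, camera nonlinearity, the
VIPA transfer function beyond Lorentzian lines, multi-order spectral
overlap, non-spherical or internally structured cells, and any coupling
between a cell's optical and mechanical parameters beyond what the
drawing distributions impose. Passing tests therefore demonstrate
correctness of the *inversion chain* under the stated signal models, not
robustness to every artifact of real instruments.

## Verified accuracy under the default study conditions

Numbers the test suite recomputes (noise-free, blur-free, calibration
divisor disabled, 512-px frames): recovered `n̄` within ±0.001, dry mass
within 2% of the closed form `Δn·V/α` (typically ±0.1%), diameter within
2% (typically +0.7%), shift within 5 MHz and linewidth within 10 MHz.
With default blur/noise/calibration the chain lands control-condition
cells at ρ ≈ 1.05 g/mL, M′ ≈ 2.45 GPa, tanφ ≈ 0.16. Spectral
repeatability at ≈32 dB SNR: SD of the fitted shift < 1 MHz over 200
replicates, comfortably inside the ≤10 MHz instrument repeatability
bound. The Welch-test power check on the control-vs-hypoosmotic shift
distributions passes p < 10⁻⁵ in roughly 70% of seeded replicates
(noncentral-t power ≈ 0.70 at these means/SDs/sample sizes), so a single
cohort comparison usually, but not always, clears that threshold.

## Known limitations

- The diameter estimator's residual size-dependent bias after the fixed
  bead calibration (above) propagates to volume (≈ ×3) for large cells.
- One spectral order only: spectra are assumed to contain one elastic
  line with both Brillouin peaks inside one FSR; multi-order frames are
  flagged, not disambiguated.
- Linewidths below the instrument response are rejected rather than
  deconvolved; a Voigt treatment of broadening is out of scope.
- Chromatic dispersion between λ_Q (632.8 nm) and λ_B (532 nm) is
  ignored (sub-10⁻³ effect on refractive index).
- Temperature dependence of all moduli is not modelled.
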
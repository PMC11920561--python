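# Methods note

This note records the physical model, the numerical choices and the known
limitations of the `hospect` package: a simulation and analysis pipeline for
image-quality harmonization of quantitative ¹⁶⁶Ho SPECT/CT across scanners
and scatter-correction methods.

## Scope

¹⁶⁶Ho imaging uses the 81 keV photopeak (15% width) flanked by two adjacent
8% scatter windows, plus a 118 keV window (12%) dominated by downscatter
from higher-energy emissions. The pipeline covers:

1. digital phantoms (homogeneous cylinder; NEMA IEC body phantom with six
   hot spheres and a cold lung insert),
2. a multi-window projection simulator with retained ground truth,
3. energy-window scatter correction (DEW, TEW, and an oracle correction),
4. OSEM reconstruction with attenuation correction and optional detector
   response modelling,
5. a five-metric suite — system sensitivity, axial-uniformity curvature,
   coefficient of variation, contrast recovery, contrast-to-noise — and
   cross-scanner aggregation.

## Phantoms

**Cylinder.** A homogeneous cylinder defined by diameter and fill volume;
length follows from the two (`L = V / (π r²)`). Presets record the fills
used at five imaging centers. Water attenuation is 0.184 cm⁻¹ at 81 keV.

**NEMA IEC body.** The interior is modelled as two half-cylinders of 80 mm
radius joined by a central box, interior length 180 mm. The box width is
fitted per preset so the modelled fillable volume equals the recorded fill
volume — this keeps activity conservation and the recorded concentrations
mutually consistent, at the cost of a slightly preset-dependent body width.
The six spheres (10–37 mm inner diameter, volumes 0.5–26.5 mL) sit on a
57.2 mm ring in a plane 70 mm from the open end; the Ø 50 mm lung insert
(0.05 cm⁻¹) runs along the axis. The nominal sphere-to-background ratio R
used for CRC is always recomputed from the recorded activities and volumes;
the fill-sheet value is kept in metadata (for one preset the two disagree,
7.4 recorded vs ≈7.1 computed, and both are retained).

**Voxelization** is a voxel-center membership test. Construction fails
loudly if a sphere receives no voxels (grid too coarse) or the grid does not
cover the phantom. At 2 mm voxels the voxelized total activity matches the
fill sheet within 0.5%.

## Projection simulator

The projector is rotation-based: the volume is rotated (trilinear
interpolation) so each view becomes an axis sum; attenuation uses reversed
cumulative sums of the rotated μ-map with a half-voxel self-attenuation
correction. Depth-dependent detector response is a Gaussian whose FWHM
follows `√(intr² + (d (L_eff + z)/L_eff)²)` with `L_eff = L − 2/μ_Pb`;
blurs are grouped by rounding σ to 0.25 pixel to bound the number of
filter passes. Two collimator presets are provided (MEGP: 3.0/1.05/58 mm;
MELP: 2.94/1.14/40.64 mm) and photopeak sensitivity scales with the
geometric efficiency `(d²/(L_eff(d+s)))²`, calibrated so the MELP system
lands near 7 cps/MBq.

Each energy window's mean projection is a mixture of three components:
the attenuated primary projection, a 100 mm-FWHM in-plane blur of it
(photopeak scatter), and a 200 mm blur of the *unattenuated* projection
(downscatter, spatially flatter). Component amplitudes per window are
configuration; the defaults make the adjacent-window contents scale with
window width (so the TEW trapezoid is nearly unbiased) and make DEW with
k = 1.05 mildly under-subtract the true photopeak contamination — the
qualitative behaviour reported for this isotope. The window totals are
normalized so that the configured per-window sensitivity is exact for any
noise-free acquisition (sensitivity closure). Counts are Poisson draws from
the mean, seeded; the noise-free component decomposition is retained as
ground truth.

The simulator is a *component-mixture* model, not particle transport:
scatter kernels are stationary Gaussians, there is no septal penetration
imaging, no dead time, and no detector energy response. It is built for
direction-of-effect and invariance studies, not for absolute dosimetry.

An image-domain shortcut (`simulate_reconstructed_volume`) emulates a
reconstructed volume directly (system blur, residual scatter background,
axial modulation `1 + A (z/L)²`, seeded noise) to test the metric suite
against planted truths.

## Scatter correction

- **DEW**: `s = k · c₁₁₈`, k = 1.05 (configurable).
- **TEW** (trapezoid): `s = w_lo c_lo + w_hi c_hi` with per-window weight
  `w = W_peak/(2 W_scatter)`; for 15% vs 8% windows w = 0.9375 ≈ 0.94, the
  value consoles report.
- **Oracle**: the simulator's true photopeak contamination (scatter +
  downscatter); stands in for transport-based corrections on real data.

Estimates are clamped nonnegative by default and are never subtracted from
the data; they enter the OSEM forward model additively.

## Reconstruction

Standard OSEM with per-subset sensitivity images, angle subsets interleaved
in bit-reversed order, additive scatter in the denominator, nonnegativity
by construction. Update counts are explicit (the study conventions are
4 iterations × 8 subsets and 10 × 8). Voxels with zero subset sensitivity
are frozen at zero with a warning. An optional Gaussian post-filter is
provided (zero-padded; count-preserving away from the volume edge).

## Metrics

- **System sensitivity**: summed window counts / (t · n · A) in cps/MBq.
- **Axial uniformity**: per-slice masked sums over the cylinder (support
  dilated 5 voxels in-plane), normalized by the profile mean, fitted with
  `c + A (x/L)²` by ordinary least squares. Three slices are trimmed at
  each profile end by default (≈ one detector-response FWHM) to keep
  partial-volume end effects out of the fit; the method ordering reported
  by the pipeline is unchanged for trims 1–3.
- **COV**: per-slice population σ/μ in a 30 mm-eroded cylinder VOI,
  averaged over slices with ≥ 10 voxels.
- **CRC**: `(C/C_B − 1)/(R − 1)` per sphere with R the nominal fill ratio
  (never re-estimated from the image); the cold lung uses R = 0, giving
  `1 − C_L/C_B`.
- **CNR**: `(C − C_B)/σ_B` (negative for cold inserts).

VOIs: spheres at true inner diameter; Ø 30 mm lung cylinder; a background
shell (radius of revolution 57 mm, thickness 37 mm, height 50 mm) centered
axially midway between the sphere plane and the far interior end, with
sphere/lung voxels excluded. VOI placement accepts a rigid transform;
moment-based registration (center of mass + principal axes) is provided,
degrading with a warning to translation-only for axially symmetric
supports, where rotation is unobservable.

Aggregation reports mean ± sample SD (ddof = 1) and range across scanners,
and pairwise percent differences under two labelled conventions: the mean
over scanners of per-scanner relative change, and the relative change of
cross-scanner means. The two differ in general and are never mixed.

## Numerical choices

- Axes are `[x, y, z]` with z the scanner axis; units mm / s / MBq;
  attenuation is stored in cm⁻¹ and converted per-voxel-path internally.
- The projector caches per-angle transmission factors in float32; images
  and updates are float64.
- Scatter-component kernels are renormalized after truncation so blurring
  preserves counts.
- NIfTI (diagonal affine) is the on-disk volume format; projection
  archives are per-window NIfTI stacks plus a schema-checked JSON sidecar;
  DICOM series are read-only inputs.
- All randomness flows from explicit integer seeds; identical seed and
  configuration reproduce bit-identical counts.

## Limitations

- Scatter/downscatter spatial models are stationary Gaussians; real
  contamination is object-dependent and asymmetric.
- The collimator model ignores septal penetration imaging and hole-pattern
  effects beyond the geometric efficiency and distance-dependent FWHM.
- The oracle correction bounds what energy-window methods could achieve in
  this simulator; it is not a Monte-Carlo transport result.
- Moment-based registration needs a clearly asymmetric support; it reports
  translation only for cylinders.
- Desk-scale grids (64³ at 4.8 mm) keep runtimes in minutes; sphere CRC at
  this resolution carries noticeable partial-volume discretization on the
  smallest spheres.
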
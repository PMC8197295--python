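# Methods

This note documents the models implemented in `spotfts`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## Optical geometry

The system is a widefield fluorescence microscope whose tube lens is a
micro-lens array (MLA) at a plane conjugate to the objective back focal
plane (BFP). Each lenslet samples a patch of the pupil and therefore images
the sample from a distinct direction. For lenslet (m, n), with half-integer
indices m, n ∈ {−2.5, …, +2.5}, pitch p referred to the BFP, and objective
focal length f₁, the viewing direction projected onto the x–z and y–z planes
makes angles

    α_m = atan( m p / √(f₁² − (m²+n²) p²) ),
    β_n = atan( n p / √(f₁² − (m²+n²) p²) ).

Two conventions deserve note, because the source hardware description leaves
them open:

- **Reference plane of p.** The pitch entering the angle formula is the MLA
  pitch multiplied by the relay demagnification (500 µm × 2.86 = 1.43 mm),
  i.e. the lenslet pitch *as seen at the BFP*, since the angles are defined
  at the objective. Only this reading keeps interior-lenslet angles inside
  the objective aperture.
- **Usable lenslets.** A lenslet is excluded when its center radius exceeds
  the pupil radius NA·f₁ (the four corner lenslets), and also when
  (m²+n²)p² ≥ f₁², where the angle expression has no real solution (the
  remaining |m| or |n| = 2.5 lenslets). With the default parameters 16 of 36
  lenslets survive both cuts. Excluded lenslets are flagged, never silently
  zeroed. Whether the physical instrument uses all 36 sub-images is unknown;
  the exclusion is configurable through the lenslet grid.

f₁ is derived from the 200 mm reference tube length convention of the stated
objective (f₁ = 200/60 mm); other manufacturers' conventions can be set via
`reference_tube_focal_mm`. Derived figures with the default configuration:
overall magnification (f_MLA/f₁)·2.86·4 = 47.36 (rounding the relay
demagnification to two decimals yields the commonly quoted 47.3; the
computed value is reported without forcing agreement), field of view
42.23 µm, camera pixel referred to the
sample 0.274 µm, lenslet diffraction limit λ/(2·NA_lenslet) = 1.235 µm at
530 nm using the lenslet width as aperture (0.874 µm using the diagonal).

## Interferogram processing

Each pixel's trace I(δ) over the OPD sweep is processed independently:

1. **Mask.** A pixel enters processing iff its maximum over the sweep
   exceeds median + k·MAD of the per-pixel maxima (k = 6 by default; the
   threshold criterion used on the real instrument is unpublished, so a
   standard robust rule is used).
2. **Detrend.** The best straight-line fit is removed (zero mean, zero
   slope), suppressing bleaching and drift.
3. **Envelope centering.** The upper envelope is a cubic spline through the
   local maxima (analytic-signal magnitude when fewer than 4 maxima exist);
   the zero-OPD burst is its peak, localized to sub-sample precision with a
   3-point parabola and shifted to δ = 0. A near-flat envelope (minimum
   above 30% of the maximum) means monochromatic light, whose burst is not
   localizable; the axis is then centered on the scan midpoint. An envelope
   peaking at the scan edge raises an error (burst not captured).
4. **Apodization.** The Norton–Beer family A(u) = Σᵢ cᵢ(1−u²)ⁱ with
   u = δ/δ_max and the literature-standard coefficient sets (medium:
   0.152442, −0.136176, 0.983734; Σcᵢ = 1 so zero OPD is unweighted).
   Medium is the default; boxcar, weak, and strong are provided.
5. **Transform.** The magnitude of Σⱼ sⱼ exp(−2πi σ δⱼ) on a uniform
   wavenumber grid. Phase is discarded deliberately: no Mertz/Forman phase
   correction is applied, matching the processing pipeline this package
   models. The default grid spans 1/750 nm⁻¹ up to the Nyquist wavenumber
   1/(2·mean step), 2048 points, configurable.

Because the translation stage has positioning nonlinearity, the δⱼ are not
uniform and the transform is a type-1 nonuniform FFT. No NUFFT library is
assumed: the implementation spreads samples onto a 2× oversampled grid with
a truncated Gaussian kernel (half-width 14 fine-grid points), FFTs, and
divides by the kernel's analytic transform. Against a direct nonuniform DFT
the relative error is ~10⁻¹², comfortably beyond the 10⁻⁶ contract the
tests enforce; on uniform axes it agrees with a plain DFT to <10⁻⁹.

**Instrument line shape.** The ILS is computed numerically: the taper is
integrated against cos(2πσδ) over the centered span on a fine wavenumber
grid and the FWHM read off by linear interpolation (grid sizes 2001 × 6001,
converged to ~10⁻⁵ relative against 4× finer grids). The stated "maximum OPD
of 200 µm" is interpreted as the total double-sided span (δ ∈ [−100, +100]
µm after centering): only this reading reproduces the known boxcar figure
1.2067/(2δ_max) = 60.3 cm⁻¹. The Norton–Beer medium ILS is 84.5 cm⁻¹ on the
same span — the medium/boxcar width ratio is 1.400 for any span — which
converts to 3.38 nm at 632.8 nm and 2.01 nm at 488 nm.

## Forward simulation

Phantoms are labeled voxel volumes (z, y, x order; isotropic voxels):

- a 6 µm bead with a stained surface shell. The stain-layer thickness is
  not published; the default is 0.8 µm, a typical value for surface-labeled
  polystyrene beads of this size, and the one consistent with the two
  qualitative observations the simulation must reproduce — the projections
  show a filled disk (blurred center above half the rim intensity) while the
  reconstructed mid-plane shows a hollow ring;
- a 0.5 µm "point" bead for resolution measurements;
- a two-compartment pollen-like phantom (green-emitting core, red-emitting
  envelope).

Emission spectra are Gaussian bands on a wavenumber grid, optionally
truncated by ideal filter edges (the default bead band peaks at 530 nm and
is cut at 512/545 nm, the emission-filter window of the modeled instrument),
or exact monochromatic lines. Spectra mix linearly along rays — incoherent
fluorescence addition — with one spectrum per phantom label.

Projection is a parallel line integral implemented by shearing: slice z is
shifted by (z − z_c)(tan α, tan β) with exact Fourier phase ramps and the
slices are summed. Shifts are periodic, so the phantom support plus the
maximum shear must fit inside the grid; violating that raises rather than
wrapping. The projection is then blurred with the lenslet PSF h(x, y):
an isotropic Gaussian with FWHM equal to the lenslet diffraction limit by
default (the physical square-aperture sinc² pattern is available and is used
as the "true" blur in end-to-end resolution tests, where the Gaussian is the
deconvolution model). Per-lenslet projections are tiled into one camera
frame in lenslet-grid order.

Interferograms follow I(δ) = B ∫ S(σ)(1 + cos 2πσδ) dσ with trapezoid
quadrature on the spectrum grid (exact cosine for line spectra), so the
noiseless zero-OPD intensity is twice the mean level. The OPD axis is
nominally uniform with seeded Gaussian jitter on interior points (endpoints
fixed, so the mean step is exact); the default jitter RMS in tests, 10 nm,
is of the order of the closed-loop repeatability of piezo stages of this
class. Camera noise is scaled-Poisson shot noise plus Gaussian read noise;
the simulation tests use ~100 photons at the brightest pixel and 2% read
noise, a dim-fluorescence EMCCD regime. EM-register excess noise,
background, and chromatic PSF variation are not modeled.

## Reconstruction

For each wavelength plane, the sub-images are (1) deconvolved with
Richardson–Lucy (multiplicative, flux-conserving; the established
scikit-image implementation; default 10 iterations), (2) Fourier-transformed
and inserted onto the tilted central plane k_z = −(k_x tan α + k_y tan β) of
a 3D Fourier volume — values are spread onto the two nearest k_z grid planes
with linear weights, accumulated together with the weights, and overlapping
insertions therefore average — (3) inverse-transformed after weight
normalization (unfilled voxels, the missing cone, stay zero), and
(4) refined with an alternating-projection positivity constraint: clip
negatives in real space, restore the measured Fourier samples, repeat
(default 50 iterations, early stop when the negativity energy falls below
10⁻⁴ of the total). The spectrum accumulated in the volume is referenced to
z′ = z − n/2 (object centered axially), which keeps it smooth in k_z so that
linear gridding is accurate; the inversion rolls the result back.

The reconstruction grid is isotropic: side = sub-image side, voxel =
sub-image pixel pitch. Sub-images are registered purely by the known lenslet
grid; no cross-correlation refinement. Deconvolution strictly precedes the
inverse projection (the order is sequential, not interleaved).

Resolution is measured as in the modeled experiment: the 1D profile through
the maximum-intensity voxel is fitted with a Gaussian and FWHM = 2.3548 σ
reported.

## What the synthetic tests do and do not show

The forward and inverse models in this package share the same projector,
the same (or a deliberately mis-specified) PSF, and noise far better behaved
than real EMCCD data with background and stray light. Consequences observed
and asserted in the test suite:

- The unrefined Fourier-slice inversion of a point bead shows the expected
  missing-cone anisotropy (axial width exceeding transverse) for moderate
  angle sets, and the positivity constraint reduces the axial smear of an
  extended shell (second-moment elongation 1.15 → 0.95 at 30° maximum view
  angle).
- With the full default pipeline on clean simulated data, however,
  Richardson–Lucy plus the positivity constraint act as a near-exact
  inverse: a 0.5 µm bead is recovered at close to its true size
  (~0.6 µm transverse), i.e. the measurement reads *object* size rather
  than *instrument* resolution, and the axial/transverse ordering can
  invert. Real acquisitions do not behave this way — PSF estimation error,
  background, registration error and EM noise keep the measured resolution
  near the diffraction limit — and this divergence between idealized
  simulation and instrument-limited practice is a known property of
  simulation studies that share the forward model with the reconstruction
  ("inverse crime"). Passing the synthetic closure tests therefore
  demonstrates the correctness of the operators, not the resolution figures
  a physical instrument would deliver.

## Problem sizes

Desk-scale defaults used throughout tests and examples: 64³ voxel volumes
(48³ for the pollen phantom at 0.5 µm voxels), 16–36 viewing angles, 320
OPD frames over 40 µm for full-pipeline closures, and 2000 frames over
200 µm for single-pixel spectroscopy, chosen so each capability is exercised
at full fidelity while any single test stays within tens of seconds.
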
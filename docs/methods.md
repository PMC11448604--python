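# Methods

`optrecon` reconstructs optical projection tomography (OPT) volumes from
wide-field projection image stacks. This note records the models the package
implements, the defaults and why they were chosen, what the built-in
simulator does and does not emulate, and the numerical decisions a
maintainer would want written down.

## Imaging model and conventions

A fluorescence OPT acquisition records P wide-field images of a rotating
sample; each image approximates line integrals of the fluorophore
distribution along straight, parallel rays. Angles are in degrees,
counter-clockwise viewed down the rotation axis; the first frame defines
θ = 0 and θ_p = p·(angular_range/P). The rotation axis is vertical in the
frame, so detector rows index z and each row yields an independent x–θ
sinogram of shape (U, P). Reconstruction proceeds slice by slice.

## Parallel-beam projector and FBP

The forward projector samples the slice along each ray at unit steps with
bilinear interpolation; the detector column grid coincides with the image x
grid. Its adjoint scatters with the identical bilinear weights, so the pair
passes the dot-product test to machine precision (~1e-16) — the property the
iterative solver's gradient correctness rests on.

FBP ramp-filters each projection in the frequency domain. The filter is
built from the spatial impulse response of the discrete ramp
(h[0] = 1/4, h[n] = −1/(πn)² for odd n), which gets the small non-zero DC
term right; projections are zero-padded to the next power of two ≥ 2U to
avoid circular-convolution bias. Apodisation windows (Shepp–Logan, cosine,
Hamming, Hann) and a fractional Nyquist cutoff are applied on top of the
ramp. Back projection is pixel-driven with linear interpolation and scaled
by π/(2P) for any uniformly sampled range: the discrete ramp carries a
factor 2, and doubling the angular range doubles the (redundant) angle sum,
so 180° and 360° data share one constant. This normalisation is absolute:
the reconstruction of a forward-projected unit disc has interior mean
1.000. Voxels outside the inscribed circle are zeroed (they are not covered
by every view). A 360° acquisition can be used whole (`full360`, the
default — conjugate rays average), folded to 180° by mirror-averaging
opposed views, or treated natively as 180° data.

Volumes are reconstructed row-by-row in chunks sized to a RAM bound;
because slices are independent the result is bit-identical for every chunk
size.

## TwIST with total-variation regularisation

Sparse-view data are reconstructed by minimising
J(x) = ½‖y − Ax‖² + λ·TV(x) with the two-step iterative
shrinkage/thresholding scheme

x_{t+1} = (1−α)x_{t−1} + (α−β)x_t + β·Ψ_λ(x_t + Aᵀ(y − Ax_t)).

A is normalised to unit spectral norm by 20 seeded power iterations before
iterating. α and β follow the standard TwIST rule for an assumed spectral
interval [ξ₁ = 1e−3, ξ_m = 1] of AᵀA: ρ = (1−√κ)/(1+√κ) with κ = ξ₁/ξ_m,
α = ρ²+1, β = 2α/(ξ₁+ξ_m). Ψ_λ is the isotropic TV proximal map computed
with a fixed number (10) of Chambolle dual iterations, followed by a
non-negativity clamp (fluorescence is non-negative; on by default). The
monotone variant is used: if the two-step candidate would raise the
objective, the plain IST step is taken instead, so the objective is
non-increasing after the first two iterates; ten consecutive increases
abort with a diagnostic. Iterations stop when the relative objective
decrease falls below `tol` (default 1e−4) or at `max_iters` (200).

λ defaults to 0.01·max|Aᵀy| per slice — scale-invariant in both the data
and the geometry — and is exposed. The warm start is a Hamming-filtered FBP
reconstruction; a zero start is available. The defaults are declared
choices, not values inherited from any particular instrument.

## Fan-beam reconstruction for focal-scanning data

A focal-scanning (liquid-lens) telecentric arm is not quite telecentric:
magnification varies approximately linearly with axial position. Fitting
apparent size vs depth of a fixed-length object gives the gradient g and
on-axis magnification m0; under the linear model m(z) = m0·D/(D−z) the
projection geometry in the central plane is a fan with origin at
D = m0/g on the optical axis (|g| < 1e−6·m0 is treated as telecentric,
D = ∞). The virtual flat detector sits in the rotation-axis plane with the
image pixel grid.

Reconstruction is the standard flat-detector fan-beam FBP: pre-weight each
projection by D/√(D²+s²), ramp-filter as in the parallel case, and
back-project along the diverging rays with the 1/W² distance weight,
W = (D−t)/D, where t is the in-beam depth of the voxel. The same π/(2P)
constant applies, and the parallel limit D → ∞ reproduces `fbp_slice` to
well under 1% RMS. Redundancy weights are 1 across the full acquired range;
exact 180° fan data would carry a small documented bias (not exploited —
the study phantoms use 360°).

When D is unknown it is estimated the way an operator would tune it — by
minimising reconstruction artifacts — but with an automated metric: for
each candidate D the slice is reconstructed, point features are detected
and Gaussian-fitted, and the artifact score is the mean bead FWHM weighted
by radial distance from the axis (off-axis beads are exactly where a wrong
origin smears tangentially). The sweep returns the arg-min and the full
curve; ties break toward larger D (closer to parallel). The metric is
unimodal around the true D on the study phantom and recovers it exactly on
a {25, 40, 50, 65, 100, ∞} mm candidate grid.

Validity is central-plane only: rows away from the lens plane of incidence
mix heights (a cone-beam effect) that this 2-D model ignores; full
cone-beam reconstruction is out of scope.

## Focal-sweep PSF and deconvolution

Fixed-focus OPT ties resolution to sample size: requiring DOF ≥ sample
radius with dof = λ/NA² and Rayleigh resolution 0.61·λ/NA gives
resolution ∝ √(λ·dof) — 38 µm for a 7 mm DOF at 550 nm. (Neither formula
is uniquely standard; this pairing is the package's documented convention
and reproduces the customary figure.) Focal scanning escapes the trade-off
by sweeping a shallow high-NA focus through the sample during each
exposure.

The 3-D PSF is modelled as a Gaussian beam: lateral σ(z) = σ₀√(1+(z/z_R)²)
with σ₀ = 0.21·λ/NA and z_R = nλ/(πNA²) — a deliberate parametric
substitution for externally generated scalar-diffraction PSFs, adequate for
the deconvolution role and fully testable. Each z-plane is normalised to
unit integral (wide-field imaging conserves in-plane energy) and weighted
by the sweep dwell time, uniform for a triangle sweep that cycles many
times per exposure. The deconvolution kernel is the axial projection of
this stack.

Richardson–Lucy deconvolution is implemented with FFT circular
convolution, which makes the per-frame flux conservation exact (the
property tests assert 0.1%); 25 iterations is the default. A Wiener filter
H*/(|H|²+NSR) is the linear alternative.

## Preprocessing

* Flat field: frame′ = (frame−offset)/(background−offset)·mean(background−offset),
  clamped at 0; rejected if background ≤ offset on more than 1% of pixels.
* Hot pixels: a pixel is replaced by its 3×3 window median when it deviates
  from it by more than 6 robust sigmas (MAD·1.4826, per frame). MAD is used
  precisely because the defects being detected would corrupt a standard
  deviation.
* Downsampling: factor×factor mean binning; pixel size scales; frames crop
  to the largest divisible region.
* Bleaching: monoexponential in projection index (a proxy for cumulative
  light dose). Per-frame foreground totals — the frame sum minus the
  background level (25th percentile) times the pixel count — are fitted as
  log I_p = a + bp and the correction multiplies frame p by s_p = e^{kp},
  k = −b. This total is scale-equivariant *and* invariant to how projected
  content redistributes with angle (mass conservation), which a thresholded
  sum is not. R² is stored; a low R² warns that the monoexponential model
  does not fit.
* Alignment: for 360° data the frame at θ+180° is the mirror, about the
  axis column, of the frame at θ. Row-band sums of a frame and the
  column-mirrored opposed frame are registered by 1-D phase
  cross-correlation (upsampled 50×); the shift equals twice the axis
  offset. Phase correlation is used deliberately: a raw correlation peak is
  biased toward zero lag by the overlap taper for spatially extended
  signals. The per-band offsets across rows give the axis tilt from the
  slope of a straight-line fit. Because in-plane rotation also mixes
  detector rows between bands, a single pass underestimates the tilt by a
  content-dependent factor (~0.9 at 190 rows); the estimate is therefore
  refined iteratively (correct a working copy, re-estimate the residual,
  accumulate — geometric convergence, 3 passes). For 180° data opposed
  pairs do not exist and only manual parameters are accepted.
  Correction applies the translation and rotation with bilinear
  interpolation and zero fill.

The documented pipeline order is flat-field → hot-pixel → bleach → align →
downsample; every step is pure and preserves shape and metadata except
downsampling.

## Phantom simulator

The generator produces three ground-truthed objects on a physical grid
(field size in mm, default 14 mm — the scale of the fan-beam study
phantom):

* beads — point-like fluorophores (default diameter 1 µm) placed
  seeded-randomly in the inscribed cylinder or at explicit positions.
  Random placement enforces an in-plane minimum separation (default 8 px) by
  rejection sampling — real bead phantoms are dilute, and unresolvable bead
  pairs would measure fusion artifacts rather than reconstruction quality.
  Sub-voxel beads are rendered as integrated Gaussians whose physical σ
  (diameter/2.3548) is combined in quadrature with a band-limiting render σ
  of 0.8 px so the object is representable on the grid without aliasing.
* disc — a uniform cylinder, the absolute-intensity calibration object.
* vessels — smooth 3-D random-walk tubes with Gaussian cross-section,
  kept inside 0.4 of the field radius; a vasculature-like object whose
  dense, z-continuous structure is what the alignment and bleaching
  estimators need.

Simulation order: geometry (parallel, or central-plane fan from distance D
— every row sees the same in-plane fan; cone-beam row mixing is not
simulated, matching the reconstruction's central-plane scope), optional
focal blur, bleaching e^{−kp}, misalignment (shift then rotate, the exact
inverse of the correction), then seeded noise (Gaussian as a fraction of
the peak, or Poisson with a photons-at-peak scale). Noise comes last so
bleach estimation sees realistic totals. All randomness derives from the
single spec seed; runs are bit-identical.

What the simulator does not emulate: camera read-noise/shot-noise
mixtures, refraction and scattering in the sample, depth-dependent blur
coupled to the rotation (the focal blur is a single sweep-averaged kernel),
and out-of-plane cone-beam mixing. Tests passing on these phantoms
therefore validate the geometry, calibration and solver logic — not
robustness to every camera artifact of real acquisitions.

## Study problem sizes

The built-in studies use deliberately modest sizes chosen as scaled
analogues of full acquisitions: the disc self-consistency test at U = 256
with 400 views over 360°; the undersampling study on a 128 px, 40-bead
slice with subsets {20, 40, 80, 200} of 400 views referenced to the
400-view FBP; the fan-beam study on a 256 px analogue of the 14 mm bead
phantom at D = 50 mm with beads on rings of 20–80 px radius; parameter
recovery on a 96×96×160 vessel stack with 32 views. On the undersampling
phantom, the noiseless sparse bead slice is the regime where TV-regularised
recovery is strongest; SSIM of 10×-undersampled TwIST matches or exceeds
2×-undersampled FBP there, reproducing the qualitative sparse-view claim at
this reduced scale.

## Numerical choices and degenerate inputs

* Bilinear interpolation throughout the projectors and alignment; the
  correlation sub-pixel step is upsampled phase correlation.
* The fan-beam weight W = (D−t)/D diverges as t → D; D ≤ field radius is
  rejected outright.
* Sinograms with a single projection are rejected by FBP (P ≥ 2) and the
  angle grid must be uniform to 1e−8 relative.
* An all-zero sinogram reconstructs to an all-zero slice; an all-zero PSF
  projection and empty volumes are errors.
* QC is report-only and never raises; with no stated saturation value the
  saturation check is skipped. The continuity score (mean absolute
  centroid shift between adjacent projections, per row) is this package's
  own quantitative stand-in for an interactive sinogram checker, with
  thresholds (0.05 saturation fraction, 2 px continuity) exposed.
* `estimate_fan_origin` with no detectable point features in any candidate
  reconstruction raises; candidates with no detections score ∞.
* SSIM uses the canonical constants (Gaussian window σ = 1.5, K1 = 0.01,
  K2 = 0.03, 11×11 support); the parameters are not uniquely standardised
  in the literature this package follows, so they are exposed. Volumes are
  scored as the mean of per-slice 2-D SSIMs. Bead FWHMs come from
  symmetric-2-D-Gaussian least-squares fits (FWHM = 2√(2 ln 2)·σ), measured
  on maximum intensity projections when evaluating volumes.

## Known limitations

* Fan-beam accuracy is central-plane only; off-plane rows inherit a
  documented cone-beam error.
* The tilt estimator's iterative refinement converges on dense, z-smooth
  content; very sparse samples (isolated beads in few rows) give noisy
  per-band offsets and poorer tilt accuracy.
* The TwIST runtime grows with the projection count and slice size; the
  adjoint-exact projector is pure NumPy and single-threaded.
* GPU acceleration is not included; all paths are CPU and deterministic.
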
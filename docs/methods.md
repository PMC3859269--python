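# Methods

This note documents the models implemented in `dbtsim`, the conventions
and defaults chosen where several reasonable options existed, and what the
synthetic study setup does and does not establish.

## Acquisition model

The system lives in "pixel units": the detector pixel pitch and the voxel
edge both default to 1, all distances are multiples of that unit, and no
physical attenuation units (cm⁻¹) are modelled.  The detector is a
stationary flat panel in the z = 0 plane, centred on the origin, with
`n_u` pixels along the scan (x) direction and `n_v` along y.  The X-ray
point source steps along a circular arc of radius
`source_to_detector_distance` about the detector centre in the x–z plane;
angles are measured from the central perpendicular.  The `n` stops are
equally spaced and include both endpoints of the scan range (step =
span/(n−1); a single stop sits at the midpoint).  The default geometry is
source radius 300, phantom centre 100 above the detector, 160×160
detector, 128×128×16 grid, 11 views over −25°…+25°.

The phantom grid is centred on the z axis with its mid-plane at
`object_to_detector_distance`; layer index k grows from the detector
toward the source, so "upper layers" are nearest the source.  With the
default magnification (300/(300−100) = 1.5) the outer corners of the
grid project beyond the 160-pixel detector at oblique angles; this
truncation is inherent to the stated geometry and is handled naturally by
the algebraic methods (missing rays simply contribute no equations).

One ray is cast per detector-pixel centre (no sub-pixel supersampling),
matching the one-equation-per-measurement structure of the ray-sum model
`Σ_j a_ij x_j = y_i`.  Projections are noiseless; a noise model is out of
scope of the default pipeline.

## Ray weights

`a_ij` is the exact Euclidean length of the intersection of ray *i* with
voxel *j*, computed by an incremental parametric (Siddon-type) traversal.
Ties at voxel corners advance every axis whose crossing parameter attains
the minimum, in the fixed order x, y, z, so the enumeration is
deterministic; zero-length sub-segments are dropped.  Per ray, the weight
sum telescopes to the in-grid segment length exactly (verified to 1e-9
relative in the tests).  Tests cross-check the weights against two
independent oracles: an exact global sort of all voxel-plane crossing
parameters (agreement ~1e-9) and a 10⁴-sample midpoint line integrator.
For the sampled oracle, agreement is asserted relative to the ray's
in-grid length, because midpoint sampling carries an absolute error of up
to about two sample spacings per voxel, which can exceed 1e-3 of an
individual sub-voxel weight while being far below 1e-3 of the ray length.

The per-view weights are assembled once into scipy CSR matrices
(~5.5 M nonzeros for the default geometry) and shared by projection and
reconstruction; the traversal and the sequential ART sweep are
numba-compiled.

## Reconstruction

One **outer iteration** is: a full data-consistency pass, then (for the
TV-regularized methods) TV descent over the whole volume, then a refresh
of the forward projection Y_P.  The loop runs `n_iterations` (NOI) times
or until ‖Y_P − Y‖₂ ≤ ε; ε defaults to 0, i.e. NOI-driven runs.

- **ART** processes all rays sequentially — views in angle order, detector
  pixels row-major — projecting onto each measurement hyperplane; rays
  with zero weight norm are skipped.  The ordering is fixed for
  reproducibility.
- **SART** processes one view at a time: residuals of all rays in the view
  are computed from the same estimate, divided by the per-ray weight sums,
  back-distributed along the rays, normalized per voxel by the summed
  weights, and applied with relaxation ω (default 1).  The normalization
  sums use absolute weights, which coincides with the standard convention
  for nonnegative tomographic weights while remaining well defined on the
  sign-indefinite random systems used as solver oracles.  `sart_update`
  accepts the degenerate ω = 0 as an explicit no-op; configuration
  validation keeps the strict 0 < ω < 2.
- **Initialization** is the all-zero volume, or the volume rasterized from
  the configured initial object list.  No nonnegativity clamp is applied
  by default (`clamp_nonnegative` enables one).

### Total variation

`TV2D`/`TV3D` sum the isotropic forward-difference gradient magnitude,
with out-of-range forward neighbours treated as equal to the edge value
(zero difference).  The functionals are nonnegative, zero exactly on
constants, and 1-homogeneous.  For descent, the gradient magnitude is
smoothed with a stabilizer δ = 1e-8 inside the square root.

TV descent moves along the negative gradient normalized to unit maximum
amplitude, so the step size is in intensity units.  Each step backtracks
(halving up to 10 times) until the objective does not increase; on
failure the descent stops.  Consequently the objective never increases
across a call — a contract the tests exercise on random volumes.

Per outer iteration the regularized methods run `tv_steps` = 20 descent
steps.  The step size defaults to 0.2× the mean absolute voxel change of
the preceding data-consistency pass, scaled by the regularization weight
`tv_weight` (default 0.8).  Tying the step to the sweep magnitude keeps
the regularization strength proportionate as the iteration converges;
both the fraction and the step count are explicit knobs
(`tv_step_size`, `tv_steps`) because no canonical values exist for them.

### PICCS

`piccs_objective(X, X_P, α) = α·TV3D(X − X_P) + (1 − α)·TV3D(X)` with the
discrete gradient as the sparsifying transform for both terms.  The
`PICCS` method runs ART for data consistency and descends this objective
instead of plain TV, using the initial volume as the prior image X_P.
With α = 0 (the default) the objective equals plain TV exactly; with an
all-zero prior it also coincides with ART+TV3D.  Arbitrary sparsifying
transforms beyond the discrete gradient are out of scope.

## Metrics

- **RMSE** √(mean((X − Y)²)).
- **CNR** |μ_signal − μ_background| / σ_background with population σ over
  caller-supplied disjoint masks; +∞ (with a warning) for a perfectly
  flat background.  No standard formula exists for CNR region choice; the
  demo uses a lesion core vs. a plain-slab patch on the layer of interest.
- **SSIM/MSSIM** computed over stride-1 sliding windows fully contained in
  the image, with population (1/n) window statistics and stabilizers
  C_m = (K_m L)², K₁ = 0.01, K₂ = 0.03.  L defaults to the joint dynamic
  range of the two images (symmetric in the arguments; 1 when both are
  constant).  The default window is the 8×8 uniform box of the original
  SSIM formulation; an odd-sized Gaussian window is available.  The
  covariance term uses the standard `2σ_xy + C₂` form, which makes
  SSIM(x, x) = 1 identically.  MSSIM is the plain mean of the local map.
  When scoring reconstructions, MSSIM and CNR are evaluated on the layer
  of interest.

## The demo phantom and what the study shows

`demo_phantom` emulates the overlapping-tissue problem: a faint tissue
slab (intensity 0.05) spanning the central layers, three low-absorption
ellipsoidal lesions (0.3) centred at 0.65·n_z — layer 10 for n_z = 16 —
and three small high-absorption spheres (1.0) at 0.85·n_z vertically
above the lesions, all scaled with the grid so a 64×64×8 variant
preserves the structure.  The arrangement is deterministic (no RNG) and
returned together with its generating primitive list.  Intensities are
arbitrary units chosen to give a strong (≈3:1 lesion:slab, ≈20:1
sphere:slab) contrast hierarchy.

On this phantom, with the default 15-iteration runs, the package
reproduces the qualitative algorithm ranking: TV regularization raises
the final layer-of-interest MSSIM of both ART and SART, and ART and SART
score within 0.05 of each other.  This is a statement about noiseless,
geometrically ideal, piecewise-constant data.  The generator does not
emulate anatomical texture, polychromatic spectra, scatter, detector
blur or dose noise, so passing these checks demonstrates correctness of
the algorithms and geometry — not clinical image quality.

## Problem sizes and determinism

The default experiment (128×128×16 voxels, 11 views of 160×160,
15 outer iterations, four methods) runs in well under a minute on one
CPU; tests and the acceptance script additionally use a 64×64×8 scaled
variant and 8³ grids for oracle comparisons.  The simulation pipeline
contains no random stage, so repeated runs are byte-identical; random
numbers appear only in the test/acceptance oracles (seeded).

## Known limitations

- Voxel membership is a centre-point test; thin structures below one
  voxel may alias, and there is no partial-volume antialiasing.
- The detector does not rotate and the source arc is planar (x–z);
  general trajectories are not modelled.
- Ordered-subset variants, matrix-free projectors and GPU execution are
  out of scope; memory holds the full sparse system (~100 MB at the
  default size).
- CNR depends entirely on the chosen regions; cross-study comparisons
  require identical region definitions.
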
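# Methods

This note records the models, conventions, parameter choices, and known
limitations behind `fibrient`, at the level of detail a maintainer or a
careful user needs. Angles are degrees, coordinates and scales are µm,
arrays are indexed (z, y, x) with z the longitudinal axis, and 3-vectors are
stored in (x, y, z) component order. Orientations are **axial** throughout:
v and −v denote the same cell axis, all comparisons use the acute angle, and
all averages of helix angles are circular means of doubled angles (the
principal-eigenvector angle of the mean outer product), never arithmetic
means — arithmetic means are wrong near the ±90° wrap.

## Orientation model

The local cell axis is estimated as the direction of least intensity
variation of the membrane signal. At each voxel,

    J(x) = G_{σ_w} ∗ ( ∇I ∇Iᵀ ),   ∇I = Gaussian-derivative at σ_g,

and the orientation is the eigenvector of J whose eigenvalue has the
smallest magnitude. Sorting is literally by |λ|; for the PSD tensors the
pipeline produces this coincides with the smallest eigenvalue. Defaults:

* `sigma_gradient_um = 2` (one voxel) — matches the optical resolution; a
  smaller scale would differentiate noise, a larger one blurs membranes away.
* `sigma_window_um = 8` (four voxels, roughly half a myocyte width) — the
  window must pool gradients from more than one membrane face to make the
  tensor full-rank across the fiber; growing it further trades noise
  robustness against transmural resolution (see the edge-bias discussion
  below). Both scales are configurable everywhere.

Voxels with no usable orientation are flagged rather than guessed: a voxel
is invalid when FA < `fa_floor` (default 0.1) or when the two smallest
eigenvalues are within `degeneracy_floor` (default 0.05) of each other
relative to the largest (a near-degenerate smallest eigen-pair means the
minimum-variation direction is arbitrary within a plane). Both floors can
be set to zero; the pseudo-resolution analysis does exactly that, because a
coarse-scale (DT-MRI-like) analysis always reports a direction. Eigenvector
signs are canonicalized (first nonzero component positive) purely for
reproducible serialization; semantics stay axial.

Fractional anisotropy uses the standard normalized eigenvalue dispersion
FA = √(3/2)·‖λ−λ̄‖/‖λ‖, defined as 0 for a zero tensor, with eigenvalues
clipped at 0 to absorb −1e-9-scale numerical negatives. Note that averaging
two orthogonal rank-1 tensors gives a planar tensor with FA = 1/√2 ≈ 0.707
(not 1/2): FA decreases under averaging of differing tensors but not
linearly.

Pseudo low-resolution mapping averages the *tensors* element-wise over
blocks (default factor 250, i.e. ~500 µm at 2 µm voxels, clamping to the
field extent) and re-runs the same eigen-analysis — mirroring how coarse
imaging integrates the underlying gradient structure, and distinctly
different from averaging orientations or angles.

## Cardiac frame and angles

From a binary wall mask, the outer boundary is the mask surface facing the
*lateral* volume border (the background component connected to the x/y
faces; the z faces are section cuts, so a lumen touching them remains
"inside"). Transmural depth is the Euclidean distance to that boundary;
the penetration direction R is the gradient of the Gaussian-smoothed depth
field (scale `normal_smooth_vox = 10` voxels), i.e. a smoothed inward
boundary normal. L is the global longitudinal axis orthogonalized against
R, and C = L × R, giving an orthonormal triad per voxel. Slices whose ring
is broken (their in-plane background all drains to the border while other
slices enclose a lumen) are warned about and flagged invalid.

Angle conventions:

* θ = arccos(|v_x| / ‖(v_x, v_y)‖), Φ = arcsin(|v_z|) — both magnitudes in
  [0°, 90°]; θ is undefined (flagged) where the XY projection vanishes.
* α_H = atan2(⟨v, L⟩, ⟨v, C⟩) mapped axially into (−90°, 90°], so +90° is
  longitudinal and the sign convention is right-handed: positive α_H tilts
  toward +L when moving along +C. Profiles are reported in [−90°, 90°]
  with no unwrapping; a transmural span that a continuous-rotation reading
  would call ~180° appears here as a ramp that crosses ±90° axially.

Sector profiles assign voxels to wedges (default 10°, combined in pairs
into 20° sectors; the reference direction is a parameter because anatomical
alignment is a manual, data-specific step) by angular position about the
mask centroid, bin them by depth (default 2 µm, one voxel, so a 50 µm
feature spans 25 bins), and average α_H axially within each (sector, bin)
over all slices. Empty bins are omitted; the voxel counts per bin are
reported and conserved. The local rate of change is a least-squares slope
over a sliding window of 15 profile samples (30 µm at the default bin).
Piecewise-linear fits are continuous (hinge basis), with breakpoints
grid-searched over the profile samples, earliest breakpoint winning ties;
the first segment's length is the outer-band extent estimate, and a fit
whose segments share one slope is flagged degenerate.

## Restoration

Richardson–Lucy deconvolution uses the multiplicative update with a
total-variation correction dividing each update by
1 − λ_TV·div(∇o/|∇o|) evaluated on the current estimate; λ_TV = 0 recovers
classic RL. Implementation choices: the estimate is initialized with the
observed image; convolutions use half-sample-symmetric ("reflect")
padding, consistent with the Gaussian filtering elsewhere in the package
and avoiding edge ringing; the TV gradient magnitude is stabilized with
ε = 1e-8; singleton axes are skipped in the TV divergence so thin stacks
work. Defaults `n_iter = 25`, `tv_weight = 0.002` are pragmatic, not
canonical, and are exposed in the configuration. With a unit-sum PSF and
interior support, the λ_TV = 0 path conserves total intensity to better
than 1e-6 relative.

Dictionary denoising learns `n_atoms = 256` unit-norm atoms of 16×16
patches by mini-batch dictionary learning on patches sampled from the
shallowest fraction (default 25%) of slices — the high-SNR layers — with
per-patch means removed and restored. Each slice is then reconstructed
from overlapping patches (stride 4 plus the far edges) sparse-coded by
orthogonal matching pursuit with at most `sparsity = 4` atoms; overlapping
reconstructions are averaged. Dictionaries are intended to be learned per
field of view, never shared across regions. Inputs already in the
dictionary's span are reproduced exactly, so the operation is idempotent on
clean data.

Stitching measures pairwise translations as the argmax of the
inverse-transformed *normalized* cross-power spectrum. For tile
registration the peak is searched only within ±25% of the tile size around
the offset implied by the nominal (stage-position) offsets — self-similar
content has false peaks further out — and only face-adjacent pairs with at
least half the nominal overlap participate; pairwise measurements are then
reconciled into global positions by least squares on the overlap graph with
tile 0 anchored at the origin (a disconnected graph is an error listing the
components). Fusion feathers overlaps linearly to the tile edge and copies
non-overlap voxels verbatim (their blend weight is exactly 1). No
flat-field or illumination correction is applied; intensity seams between
fields of view are out of scope.

## Tractography

Seeds are drawn uniformly (seeded RNG, at most 25,000) from voxels that are
valid and inside the boundary mask. Each seed grows a forward and a
backward line — the field is axial, so both senses are physical — merged
into one polyline. The integrator is a fixed-step midpoint (RK2) scheme:
a plain Euler step accumulates O(h²/r) radial drift that visibly opens
circular trajectories at phantom radii, while RK2 closes a full revolution
to a fraction of a step. At every evaluation the eight neighboring axial
vectors are sign-aligned to the running direction *before* trilinear
weighting (averaging unaligned axial vectors cancels them); a
nearest-voxel mode is available for strict fidelity to per-voxel stepping.
A line terminates on leaving the mask, entering an invalid voxel, turning
more than 60° in one step, or reaching the point cap. Glyphs subsample the
valid field on a regular stride (default 12), raising the stride minimally
if the 75,000-vertex cap would be exceeded; the color scalar is
arccos(|v_z|), proportional to the out-of-plane angle. The parula-like
colormap ships as an interpolated 9-anchor lookup table in the code.

## Synthetic phantoms

The generator's role is to provide *exactly known* ground truth under
realistic imaging degradations, not photorealistic myocardium.

* **Straight bundle**: hexagonally packed hollow tubes (lattice spacing =
  one cell diameter, default radius 6 µm) along an arbitrary axis, rendered
  as Gaussian membrane shells (FWHM = membrane thickness, default 2 µm)
  over a low background plateau (0.1).
* **Helical annulus**: a cylindrical wall (defaults: outer radius 190 µm,
  wall 120 µm, grid 64×200×200 at 2 µm voxels) whose fiber direction at
  normalized depth d is the circumferential direction rotated by
  `alpha_profile(d)` within the wall tangent plane, optionally overridden
  by a constant-angle outer band. Membranes are rendered as a
  **fiber-aligned ridge texture**: band-limited noise repeatedly averaged
  with itself advected one step forward and backward along the prescribed
  field (a line-integral-convolution-style operation; grain σ = 1 voxel,
  step 2.5 voxels, 24 sweeps ≈ 17 µm along-fiber correlation, the scale of
  a myocyte). The positive excursions read as membrane sheets between
  fiber-aligned tubes, and — crucially — the texture's direction of least
  variation equals the prescribed field *exactly*, so the recorded ground
  truth is analytic. Deterministic sheet families were rejected:
  concentric cylindrical sheets leak gradient variance into the
  circumferential (but not longitudinal) direction across the tensor
  window at phantom-scale curvature, biasing α_H toward the longitudinal
  axis by several degrees, and helical sheets require a quantized winding
  number that aliases wherever the profile is steep. The texture is
  z-periodic (the prescribed field is z-invariant), preserving fiber
  continuity at the stack faces.

Degradation models the microscope: convolution with a (default Gaussian,
σ = 2 µm) PSF, exponential depth attenuation (default 0.5 at the deepest
slice), Poisson shot noise (default 50 expected photons at unit intensity)
plus Gaussian read noise (σ = 2 photons), all deterministic given the seed.
The geometry itself is deterministic given the spec (including its texture
seed); the degradation seed is separate.

`GroundTruth.membrane` marks bright-ridge voxels; per-voxel orientation
comparisons are evaluated there, where a real analysis would trust the
signal. Profile statistics use all valid wall voxels — the texture carries
orientation signal everywhere in the wall.

## What the phantoms do and do not show

The annulus is axisymmetric, its profile is steeper (1°/µm) than a real
ventricular wall (~0.2°/µm), its wall is thinner, and its curvature is far
higher; real tissue adds branching cells, vessels, collagen, illumination
seams between fields of view, and anisotropic PSFs. Passing the recovery
tests therefore demonstrates the *machinery* — restoration, tensor
estimation, frame construction, profiling, fits — under controlled
degradations at a validation scale (~5–6° mean orientation error on
membrane voxels) comparable to what hand-segmented-cell validation yields
on real data; it does not certify accuracy on any particular tissue.

Two systematic effects are worth knowing when reading phantom numbers.
Near the wall surfaces the tensor window is one-sided, so estimated angles
are pulled toward mid-wall values over roughly one window scale — the edge
bins of transmural profiles inherit a bias proportional to the profile
slope. And at a sharp band edge, individual 20° wedge sectors sample the
transition raggedly (bin populations are small and fiber-correlated), so
transition statistics are measured on the pooled full-circle profile,
which is stable; on real, non-axisymmetric hearts the wedge width would
instead be chosen to balance angular resolution against bin population.

## Numerical and interface choices

* Eigen-decomposition is `numpy.linalg.eigh` batched per voxel; outputs
  inherit float32 storage from the tensor field (float64 in → float64 out).
* Block averaging uses exact ragged-edge means (`add.reduceat`), never
  zero-padding.
* Depth is EDT-based with a half-voxel surface offset; centroids are
  intensity-free centers of mass.
* Volumes travel as multi-page TIFF (ImageJ-style spacing metadata; a
  (1,1) resolution tag is treated as a placeholder, not a calibration),
  orientation fields as 3-channel NRRD (xyz) with a sibling validity TIFF,
  tensors as 6-channel NRRD (xx,xy,xz,yy,yz,zz), profiles as CSV, fits and
  offsets and provenance as JSON, tract output as legacy ASCII VTK. The
  NRRD and VTK writers are minimal, self-contained implementations of
  those container formats (raw little-endian NRRD; ASCII polydata).
* Every CLI stage writes a provenance record (stage, parameter echo, input
  SHA-256 hashes, version, timestamp) and a config snapshot; a single seed
  in the configuration governs all stochastic outputs.

## Known limitations

No blind PSF estimation, flat-field correction, OME metadata, AHA-segment
registration, ventricle labeling, or multi-fiber voxel models. The
structure tensor assumes one dominant orientation per window; intersections
and branch points are flagged by the degeneracy test rather than resolved.
Streamline step size and termination thresholds are conventions, not
measurements. The dictionary-learning stage is seeded and deterministic on
a given platform, but mini-batch atom order may differ across BLAS builds;
only the reconstruction, not atom identity, should be relied upon.
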
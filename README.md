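# fibrient

Micrometer-scale cardiomyocyte orientation recovery from membrane-stained 3D
image stacks.

Heart ventricular walls are packed with elongated cardiomyocytes whose
long-axis arrangement — classically summarized by the transmural course of
the **helix angle** α_H — governs contraction mechanics and electrical
conduction. Whole-heart diffusion MRI resolves this arrangement only at the
millimeter scale; confocal imaging of cleared, membrane-stained (WGA) tissue
at ~2 µm isotropic voxels resolves it at the scale of single cells, but the
signal lives exclusively on cell boundaries and arrives noisy, blurred, and
in overlapping fields of view. `fibrient` implements the full computational
path from such stacks to quantitative fiber architecture:

1. **Restoration** — Richardson–Lucy deconvolution with total-variation
   regularization; unsupervised denoising with a sparse 256-atom dictionary
   of 16×16 patches learned from the shallow (high-SNR) slices; assembly of
   overlapping fields of view by phase correlation in the Fourier domain
   with global least-squares reconciliation and feathered blending.
2. **Orientation** — at every voxel the structure tensor
   J = G_w ∗ (∇I ∇Iᵀ) is computed from Gaussian-derivative gradients; the
   cell long axis is the eigenvector of the eigenvalue of smallest
   magnitude (the direction of least intensity variation), graded by
   fractional anisotropy FA = √(3/2)·‖λ−λ̄‖/‖λ‖. Element-wise block
   averaging of tensors emulates coarse (DT-MRI-like) acquisitions.
3. **Cardiac geometry** — from a wall mask: per-voxel transmural depth and
   the orthonormal frame {C, L, R} (circumferential, longitudinal, inward
   penetration); the angle maps θ, Φ, and α_H = atan2(⟨v,L⟩, ⟨v,C⟩) in
   [−90°, 90°]; wedge-sector transmural profiles of the axial-mean α_H;
   sliding-window rates of change and continuous piecewise-linear fits that
   measure the extent of the thin outer-wall longitudinal band.
4. **Visualization** — sub-sampled orientation glyphs (every 12th voxel,
   capped at 75,000 vertices) and bidirectional, mask-bounded streamlines,
   exported as legacy VTK polydata and CSV, colored by Φ.

Because axial orientations have no sign (v ≡ −v), every consumer treats the
field axially: angular errors use the acute angle, profile means are
axial/circular means, and streamlines sign-align the field along each line.

A first-class **phantom generator** makes all of this testable without
microscope data: hexagonally packed membrane-tube bundles with a constant
known axis, and annular "ventricle wall" phantoms whose fiber field follows
a prescribed transmural helix-angle profile (optionally with a thin
constant-angle outer band), rendered as fiber-aligned membrane textures and
degraded with PSF blur, depth attenuation, and Poisson/Gaussian noise.

## Worked example

```python
import numpy as np
import fibrient as fb

# annular wall phantom: helix angle -60..+60 deg across a 120 um wall,
# plus a 50 um outer band fixed at 80 deg
spec = fb.PhantomSpec(outer_layer=(50.0, 80.0))
vol, gt = fb.make_helical_annulus(spec)

# imaging degradation and restoration
psf = fb.gaussian_psf(2.0, spec.voxel_size_um)
noisy = fb.degrade_volume(vol, psf.normalized(), seed=1)
restored = fb.richardson_lucy_tv(np.clip(noisy, 0, None), psf)

# orientation and helix angle
tf = fb.compute_structure_tensor(restored, voxel_size_um=2.0)
field = fb.smallest_eigenvector_field(tf, mask=gt.mask)
frame = fb.build_wall_frame(gt.mask, voxel_size_um=2.0)
alpha = fb.compute_helix_angle(field, frame)

mean, sd, _ = fb.angular_error(
    field, fb.OrientationField(gt.orientation, gt.mask, 2.0), gt.membrane)
print(f"orientation error vs ground truth: {mean:.2f} +/- {sd:.2f} deg")

profile = fb.sector_profile(
    alpha, frame,
    fb.SectorSpec(wedge_width_deg=360.0, wedges_combined=1), gt.mask)[0]
fit = fb.piecewise_linear_fit(profile, n_segments=3)
print(f"outer-band extent estimate: {fit['segment_lengths_um'][0]:.0f} um")
```

prints:

```
orientation error vs ground truth: 5.69 +/- 6.28 deg
outer-band extent estimate: 44 um
```

i.e. the structure tensor recovers the prescribed per-voxel orientations to
under 6° on membrane voxels despite blur and shot noise (the spread comes
mostly from the sharp band edge, where orientations genuinely mix), and the
piecewise fit of the transmural profile locates the 50 µm outer band to
within its own smoothing resolution.

The same stages are available as a shell tool:

```sh
fibrient phantom --outer-layer 50um:80 --seed 7 --out run/ph
fibrient deconv  --input run/ph/phantom.tif --out run/dc
fibrient orient  --input run/dc/deconvolved.tif --out run/or
fibrient angles  --orientation run/or/orientation.nrrd --mask run/ph/mask.tif --out run/an
fibrient profile --orientation run/or/orientation.nrrd --mask run/ph/mask.tif --out run/pr
fibrient tract   --orientation run/or/orientation.nrrd --mask run/ph/mask.tif --out run/tr
fibrient validate        # phantom -> restore -> orient; exits 0 iff error < 6 deg
```

Every stage writes its outputs with a provenance record (input hashes,
parameters, software version) and a config snapshot, so any stage can be
re-run from its on-disk inputs alone.

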
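# Methods

This note documents the models, parameter choices and numerical details
behind `penna3d`, and what the synthetic validation does and does not
demonstrate.

## Geometry conventions

All grids use index order `(i, j, k)` for the `(x, y, z)` voxel axes and
one affine everywhere: `world = origin + axes @ (index * spacing)`, with
`axes` orthonormal columns and `spacing` in mm.  Direction vectors are
axial quantities (v ≡ −v); angles between directions are always folded
to [0°, 90°] via `arccos(|a·b|/‖a‖‖b‖)`.  Missing vectors are marked by
NaN components; the zero vector is a legal pre-normalization direction
and is never used as a missing marker.

Intensities are normalized to 0–255 on load. The vesselness sensitivity
`c = 15` is calibrated to that scale; wider-typed sources (e.g. 16-bit
TIFF) are rescaled linearly and the factor recorded.

## Reconstruction

- **Temporal offset**: both streams (line position in the image,
  encoder reading) are linearly detrended and the lag maximizing their
  normalized cross-correlation is returned in seconds (positive =
  image lags encoder).  Constant series are an error, not a zero.
- **Grid**: PCA of the 4·n_frames world-space frame corners.  Axis
  signs are fixed against the image axes and the sweep direction (ties
  toward +z) and the basis is made right-handed, so repeated runs give
  a reproducible orientation.
- **Binning**: each frame pixel goes to its nearest voxel; voxels hit
  by several pixels take the arithmetic mean (order-independent — the
  acquisition gives no reason to prefer late or early frames).  A
  second pass assigns each empty voxel the value of its nearest filled
  voxel within a 3-voxel search radius (configurable); voxels beyond
  that radius are flagged as outside the swept region and left 0.
- **Pose interpolation**: linear in translation; rotation matrices are
  interpolated entrywise and re-projected onto SO(3) by polar
  decomposition.  Sweeps of the scanner are near-linear, so a slerp
  would change results below voxel scale.

## Fascicle detection

- **Vesselness** (per sagittal slice, `yz` for muscle / `xz` for
  phantom): Gaussian-derivative Hessian at a single scale σ (2 px
  muscle, 3.5 px phantom), γ = 2 scale normalization (responses × σ²),
  reflect boundaries, eigenvalues ordered |λ₁| ≤ |λ₂|, bright-on-dark
  polarity (V = 0 where λ₂ ≥ 0), β = 0.5, c = 15.  σ is in *pixels* of
  the slice grid; the in-plane anisotropy of a sagittal slice (e.g.
  0.17 vs 0.66 mm) is deliberately not compensated — the later
  voxel-size scaling of the direction components performs the
  anisotropy correction for the orientation estimate.  A single scale
  is evaluated because one σ per data type is specified; a multi-scale
  maximum can be emulated by calling `frangi_slice` per scale.
  Derivative kernels are truncated at 8σ so that constant images give
  an exactly zero response.
- **3D directions**: the re-stitched filtered volume is smoothed with
  an isotropic (in voxels) 3D Gaussian, default σ = 2 voxels
  (config-exposed; the value is not critical between 1.5 and 3 on the
  synthetic scenes), the Hessian is formed from Gaussian second
  derivatives, and per voxel the eigenvector of the smallest-*magnitude*
  eigenvalue is taken.  Along a bright tube the second derivative is
  ≈ 0 along the axis and strongly negative across it, so the literal
  signed minimum would pick a cross-fiber direction; a `mode="signed"`
  flag retains the literal reading for auditability.  Voxels whose two
  smallest eigenvalue magnitudes are within 5 % of the largest are
  flagged degenerate (e.g. isotropic blobs), not errored.  Eigenvector
  signs are canonicalized into the hemisphere of the muscle long axis
  (ties toward +z, then +y, then +x) so sums and means are stable.
- **Pruning cascade** (in order):
  1. binarize the filtered volume at 10 % of its maximum (a voxel
     exactly at the cutoff is kept) and intersect with the compartment
     mask eroded `shrink_voxels` times (6-connected structuring
     element; default 10 for muscle to avoid epimysium responses, 0
     for the phantom which has no epimysium);
  2. multiply direction components elementwise by the voxel sizes and
     drop vectors shorter than 50 % of the field maximum — with
     anisotropic voxels this removes directions dominated by the
     fine-spacing axes, i.e. noise-driven in-plane estimates;
     survivors are re-normalized to unit length;
  3. remove voxels with fewer than 18 non-missing neighbors in their
     26-neighborhood, in a single simultaneous pass over the input
     field (a voxel with exactly 18 is kept) — this strips the
     sphere-like responses at the end points of detected lines.
- **Vector smoothing**: per component, minimize
  ‖W^{1/2}(ẑ−z)‖² + s‖Δẑ‖² with Δ the discrete Laplacian under
  reflective boundaries, solved spectrally by DCT-II
  (ẑ = IDCT(Γ∘DCT(z)), Γ = 1/(1+sΛ²)).  Missing voxels get weight 0
  and are handled by an over-relaxed fixed-point iteration (relaxation
  1.75) whose fixed point solves the penalized system exactly; the
  suite verifies agreement with a dense sparse-algebra solve to 1e-8.
  Defaults: s = 35 for the detected field, s = 0.5 for whole-muscle
  extrapolation, tolerance 1e-5 on the relative update, 100 iterations
  maximum.  An optional bisquare reweighting pass (`robust=True`) is
  available but off by default: on fields that are constant up to
  noise the MAD-based residual scale becomes so small that legitimate
  orientation variation is down-weighted, which measurably worsened
  accuracy on the synthetic phantom.
- **Muscle filling**: componentwise linear interpolation (Delaunay)
  onto mask voxels inside the support's convex hull — support evenly
  subsampled to at most 5000 points, which changes recovered mean
  pennation angles by < 0.001° on the synthetic muscle while keeping
  the triangulation fast — then the spline smoother with s = 0.5 for
  the voxels outside the hull, then re-normalization to unit vectors.

## Quantification

Pennation angle is the folded angle between each voxel direction and
the aponeurosis direction (first principal axis of the aponeurosis
voxel cloud, sign-fixed along the muscle long axis).  Per-compartment
summaries resample the angles to n = 5000 voxels, without replacement
when enough voxels exist (flagged otherwise), deterministically per
seed.  Phantom statistics compare every direction of one compartment
with every direction of the other; above 10⁷ pairs a seeded uniform
subsample of pairs is used and flagged.  Because the term "relative
error" is ambiguous for angles, both a dimensionless per-pair ratio
|θ−θ_true|/θ_true and its degree-scaled form are reported.  Muscle
volume is voxel count × voxel volume (cm³).

## Synthetic scenes

The generators define the validation conditions; their defaults are
fixed and the test suite runs against them.

**Wire phantom** — two wire groups spanned between parallel walls with
2.5 mm hole pitch: a 3 × 6 array and a horizontal 2-wire pair, 0.1 mm
wire diameter, inter-group angle 10.78° split symmetrically about the
sweep axis, in water.  The imaged sub-region is 24 × 12 × 48 mm at
0.14 × 0.14 × 0.37 mm voxels (≈ 172 × 87 × 131); this is a desk-scale
stand-in for a full tank scan — large enough that each wire crosses
> 100 slices, small enough that one trial runs in ~20 s on one CPU.
Wires are rasterized as tubes anti-aliased by fractional in-plane
coverage, so the centerline is the brightest structure before noise.
The segmentation slabs around each group stop 3 mm short of the z
faces: wires leave the imaged region through those faces, and a real
segmentation never abuts the reconstruction boundary (at the boundary
the reflective Hessian padding would fold the wire onto its mirror
image and bias directions toward the sweep axis).

**Pennate muscle** — an ellipsoidal envelope (semi-axes 8 × 10 × 35 mm,
y = depth, z = long axis) split by a 1 mm central aponeurosis sheet at
y = 0; each compartment carries bright perimysium lines along the
programmed fascicle direction (superficial +θs, deep −θd in the yz
plane), arranged on a 2 mm square grid perpendicular to the line
direction with 0.4 mm line width, at 0.17 × 0.17 × 0.66 mm voxels.
Lines are modeled as tubes rather than sheets because the orientation
estimator resolves tube axes uniquely; sheet-like perimysium would be
rotationally degenerate within the sheet plane.

**Degradation model** — anisotropic in-frame Gaussian PSF (axial
0.2 mm, lateral 0.35 mm), display-gain renormalization after the blur
(a 0.1 mm reflector otherwise renders at a contrast no B-mode display
shows), multiplicative Gaussian noise (σ = 0.2) as a log-compressed
speckle surrogate, additive Gaussian noise (σ = 3 gray levels), clipped
to [0, 255].  This stresses the detector with blur, contrast coupling
and voxel-scale noise but is *not* an acoustic simulation: it has no
coherent interference pattern, no depth-dependent attenuation or
focusing, no shadowing, and no refraction.  Passing the synthetic
validation therefore demonstrates the correctness and noise tolerance
of the computational pipeline, not performance on tissue; transfer to
muscle additionally assumes fascicles behave like tubular reflectors.

## Validation targets and problem sizes

The acceptance script runs 11 phantom trials (seeds derived from
`--seed`) at the defaults above and reports the pooled mean absolute
pairwise-angle error and the mean absolute mean-direction-angle error.
The pytest suite bounds these at 0.92° and 0.68° respectively — the
accuracy level demonstrated in the physical phantom experiment the
workflow is modeled on — and further checks programmed pennation
recovery (5°/10° within 1° at low noise, ≈ 30 s), the smoother against
dense solves on ≤ 20³ grids, analytic cylinder direction recovery
within 1°, and 90°-rotation equivariance of the whole pipeline.

## Known limitations

- Orientations only: no tractography, fascicle lengths or curvature.
- The smoother's reflective boundary makes directions within ~3σ of a
  segmentation boundary less reliable; the end-point pruning removes
  most but not all of these voxels.
- `frangi_slice` evaluates one scale; vessels much thinner or thicker
  than σ respond weakly.
- Segmentation masks are inputs; no automatic segmentation is
  provided.
- The pose model assumes near-linear sweeps; strongly curved freehand
  trajectories would need slerp interpolation and a finer grid search
  in the temporal calibration.
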
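# penna3d

3D muscle fascicle orientations and pennation angles from freehand 3D
ultrasound.

Architectural parameters of skeletal muscle — above all the pennation
angle, the angle between a fascicle and its aponeurosis — determine how
much force a muscle can generate and how fast it can contract.  2D
B-mode ultrasound only ever measures a projection of the true 3D
fascicle arrangement and is highly sensitive to probe alignment.
`penna3d` implements a full 3D workflow for researchers in muscle
physiology and biomechanics:

1. **Reconstruction** — a stack of pose-tracked 2D B-mode frames is
   temporally aligned to the position encoder by cross-correlation,
   a reconstruction grid is defined by a PCA of the frame corner
   coordinates, and frame pixels are binned into voxels by nearest
   neighbor with a nearest-neighbor hole fill
   (voxel sizes 0.17 × 0.17 × 0.66 mm for muscle,
   0.14 × 0.14 × 0.37 mm for phantom data).
2. **Fascicle detection** — within user-supplied segmentation masks,
   each sagittal slice is enhanced with a single-scale Frangi-type
   vesselness filter (Hessian eigenvalues λ₁, λ₂ with |λ₁| ≤ |λ₂|):

   V = exp(−(λ₁/λ₂)² / 2β²) · (1 − exp(−(λ₁²+λ₂²) / 2c²)),  λ₂ < 0

   with σ = 2 px (muscle) or 3.5 px (phantom), β = 0.5, c = 15.  The
   re-stitched filtered volume is smoothed with a 3D Gaussian and its
   Hessian eigen-decomposed per voxel; the eigenvector of the
   smallest-magnitude eigenvalue is the local fascicle direction.
   A pruning cascade (binarization at 10 % of the maximum, compartment
   shrinking, voxel-size scaling with 50 %-length pruning, removal of
   voxels with < 18 non-empty neighbors) strips spurious directions,
   and a missing-aware penalized-least-squares spline smoother
   (DCT spectral solver, s = 35) regularizes the surviving vector
   field.  Fields can be interpolated/extrapolated over the whole
   muscle (linear interpolation + smoother with s = 0.5) and exported
   as legacy-VTK vector fields.
3. **Quantification** — per-voxel pennation angles
   θ = arccos(|d·a|/‖d‖‖a‖) against the aponeurosis PCA direction,
   resampled per-compartment summaries (n = 5000), muscle volume from
   segmentation masks, and wire-phantom angle statistics.

A synthetic data module generates the two validation scenes with exact
ground truth: a wire phantom (a 3 × 6 wire array and a 2-wire pair at
2.5 mm hole pitch, 0.1 mm wires, known inter-group angle 10.78°) and a
two-compartment pennate muscle with bright perimysium lines.

## Worked example

```python
from penna3d import WirePhantomSpec, generate_wire_phantom, run_phantom

vol, truth = generate_wire_phantom(WirePhantomSpec(seed=1))
stats, field_a, field_b = run_phantom(vol, truth)
print(f"true inter-group angle : {stats.truth:.2f} deg")
print(f"detected voxels        : {field_a.n_support()} (group A), {field_b.n_support()} (group B)")
print(f"mean pairwise angle    : {stats.mean_angle:.2f} +/- {stats.sd_angle:.2f} deg")
print(f"mean absolute error    : {stats.mean_abs_error:.2f} deg")
print(f"mean-direction angle   : {stats.mean_direction_angle:.2f} deg "
      f"(error {stats.mean_direction_abs_error:.2f} deg)")
```

prints

```
true inter-group angle : 10.78 deg
detected voxels        : 47691 (group A), 5886 (group B)
mean pairwise angle    : 10.69 +/- 1.02 deg
mean absolute error    : 0.53 deg
mean-direction angle   : 10.69 deg (error 0.09 deg)
```

The generator spans two wire groups at exactly 10.78° through a
simulated water tank, degrades the volume with an ultrasound-like point
spread function and speckle-style noise, and the pipeline recovers the
wire directions: every pairwise angle between the two groups deviates
from the truth by ~0.5° on average, and the angle between the two
groups' mean directions is accurate to ~0.1°.

The same works from the shell:

```sh
penna3d simulate phantom --seed 1 --out sim/
penna3d detect --vol sim/volume.mha --compartment sim/mask_A.mha --phantom --out sim/a.vtk
penna3d detect --vol sim/volume.mha --compartment sim/mask_B.mha --phantom --out sim/b.vtk
penna3d phantom-stats --field-a sim/a.vtk --field-b sim/b.vtk --truth 10.78
```

The exported `.vtk` files load directly into ParaView for glyph or
streamline visualization.

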
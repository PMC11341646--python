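"""Synthetic test scenes with known ground truth.

Two generators emulate the data the detection pipeline is designed for:

* a wire phantom — two groups of thin bright wires (a 3x6 array and a
  2-wire pair, 2.5 mm hole pitch, 0.1 mm wire diameter) spanned between
  parallel walls at a known inter-group angle, immersed in water;
* a two-compartment pennate muscle — an ellipsoidal envelope split by a
  bright central aponeurosis sheet, with bright perimysium lines running
  at a programmed pennation angle on either side.

Both return the rendered :class:`~penna3d.core.Volume` together with a
:class:`GroundTruth` holding the exact directions, masks and angles, so
they double as the package's oracle for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DirectionField, MaskVolume, Volume, folded_angle_deg

__all__ = [
    "SpeckleParams",
    "WirePhantomSpec",
    "PennateMuscleSpec",
    "GroundTruth",
    "generate_wire_phantom",
    "generate_pennate_muscle",
    "add_speckle",
]


@dataclass
class SpeckleParams:
    """Ultrasound-like degradation: PSF blur plus speckle-style noise.

    ``psf_sigma`` is (axial, lateral) in mm — axial is the in-frame
    depth direction (y), lateral the in-frame width direction (x).
    Multiplicative Gaussian noise stands in for log-compressed speckle;
    a small additive term models electronic noise.
    """

    psf_sigma: tuple[float, float] = (0.2, 0.35)
    multiplicative_sigma: float = 0.2
    additive_sigma: float = 3.0
    # receiver/display gain: after PSF blur, restore the peak intensity of
    # the clean scene (sub-resolution reflectors like 0.1 mm wires would
    # otherwise render at a contrast no B-mode display shows)
    normalize_gain: bool = True

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.psf_sigma) or self.multiplicative_sigma < 0 \
                or self.additive_sigma < 0:
            raise ValueError("speckle sigmas must be >= 0")

    @classmethod
    def off(cls) -> "SpeckleParams":
        return cls(psf_sigma=(0.0, 0.0), multiplicative_sigma=0.0, additive_sigma=0.0)

    @classmethod
    def low(cls) -> "SpeckleParams":
        """Mild degradation: PSF blur with weak noise."""
        return cls(psf_sigma=(0.2, 0.35), multiplicative_sigma=0.02, additive_sigma=1.0)


@dataclass
class WirePhantomSpec:
    """Wire phantom scene description.

    Group A is a ``rows x cols`` array of parallel wires (rows offset in
    y, columns in x by ``hole_pitch``); group B is a horizontal pair.
    The two groups lie in planes of constant y and run predominantly
    along z (the sweep direction), tilted symmetrically in the xz plane
    so that the angle between them is exactly ``inter_group_angle``.
    ``extent_mm`` is the imaged sub-region of the water tank; the
    physical wires (``wall_separation`` long) are rasterized only where
    they cross it.
    """

    wall_separation: float = 200.0
    hole_pitch: float = 2.5
    group_a_shape: tuple[int, int] = (3, 6)      # (rows in y, cols in x)
    group_a_center: tuple[float, float] = (0.0, -2.5)  # (x, y) mm at z=0
    group_b_n: int = 2
    group_b_center: tuple[float, float] = (0.0, 3.5)
    wire_diameter: float = 0.1
    inter_group_angle: float = 10.78
    intensities: tuple[float, float, float] = (10.0, 255.0, 10.0)  # background, wire, water
    extent_mm: tuple[float, float, float] = (24.0, 12.0, 48.0)
    mask_z_margin_mm: float = 3.0  # segmented wire region ends short of the z faces
    spacing: tuple[float, float, float] = (0.14, 0.14, 0.37)
    noise: SpeckleParams = field(default_factory=SpeckleParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inter_group_angle < 90:
            raise ValueError("inter_group_angle must be in (0, 90) degrees")
        if self.hole_pitch <= self.wire_diameter:
            raise ValueError("hole_pitch must exceed wire_diameter")
        if self.group_a_shape[0] < 1 or self.group_a_shape[1] < 1 or self.group_b_n < 1:
            raise ValueError("both wire groups must be non-empty")

    def group_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact unit directions of the two groups (angle split evenly)."""
        half = np.radians(self.inter_group_angle / 2.0)
        d_a = np.array([np.sin(half), 0.0, np.cos(half)])
        d_b = np.array([-np.sin(half), 0.0, np.cos(half)])
        return d_a, d_b

    def wire_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """(x0, y0) of each wire at z=0, per group, shape (n, 2)."""
        rows, cols = self.group_a_shape
        cx, cy = self.group_a_center
        xs = (np.arange(cols) - (cols - 1) / 2.0) * self.hole_pitch + cx
        ys = (np.arange(rows) - (rows - 1) / 2.0) * self.hole_pitch + cy
        a = np.array([(x, y) for y in ys for x in xs])
        bx, by = self.group_b_center
        xb = (np.arange(self.group_b_n) - (self.group_b_n - 1) / 2.0) * self.hole_pitch + bx
        b = np.array([(x, by) for x in xb])
        return a, b


@dataclass
class PennateMuscleSpec:
    """Two-compartment pennate muscle scene description.

    An ellipsoidal envelope (semi-axes in mm; y is the depth axis, z the
    muscle long axis) is split by a central aponeurosis sheet in the
    y=0 plane.  Each compartment contains bright perimysium lines
    running in the yz plane at the programmed pennation angle to the
    aponeurosis direction (+z), arranged on a square grid of pitch
    ``fascicle_pitch`` in the plane perpendicular to the line direction.
    """

    semi_axes: tuple[float, float, float] = (8.0, 10.0, 35.0)
    envelope_exponent: float = 2.0
    apo_thickness: float = 1.0
    apo_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    pennation_superficial: float = 5.0
    pennation_deep: float = 10.0
    fascicle_pitch: float = 2.0
    line_width: float = 0.4
    intensities: tuple[float, float, float, float] = (10.0, 40.0, 220.0, 255.0)
    # background, muscle tissue, perimysium line, aponeurosis
    margin_mm: float = 2.0
    spacing: tuple[float, float, float] = (0.17, 0.17, 0.66)
    noise: SpeckleParams = field(default_factory=SpeckleParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.pennation_superficial, self.pennation_deep):
            if not 0 <= p <= 45:
                raise ValueError("pennation angles must be in [0, 45] degrees")
        if self.fascicle_pitch <= self.line_width:
            raise ValueError("fascicle_pitch must exceed line_width")
        if self.apo_thickness >= 2 * self.semi_axes[1]:
            raise ValueError("aponeurosis thicker than the envelope depth")

    def compartment_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """True unit fascicle directions (superficial y>0, deep y<0)."""
        ts = np.radians(self.pennation_superficial)
        td = np.radians(self.pennation_deep)
        d_sup = np.array([0.0, np.sin(ts), np.cos(ts)])
        d_deep = np.array([0.0, -np.sin(td), np.cos(td)])
        return d_sup, d_deep


@dataclass
class GroundTruth:
    """Oracle container: exact directions, masks and angles of a scene."""

    directions: dict[str, np.ndarray]
    masks: dict[str, MaskVolume]
    inter_group_angle: float | None = None
    direction_field: DirectionField | None = None
    angle_map: np.ndarray | None = None
    aponeurosis_mask: MaskVolume | None = None
    aponeurosis_direction: np.ndarray | None = None


def _grid_coords(extent: tuple[float, float, float], spacing) -> tuple[np.ndarray, ...]:
    """Centered 1D coordinate arrays and the grid origin."""
    dims = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, spacing))
    coords = tuple(
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(dims, spacing)
    )
    return coords


def add_speckle(vol: Volume, p: SpeckleParams, seed: int) -> Volume:
    """Degrade a clean volume with PSF blur and speckle-style noise.

    Blur with the anisotropic in-frame PSF, multiply by (1 + Gaussian
    noise), add Gaussian noise, clip to [0, 255].  Deterministic given
    the seed; all-zero sigmas reduce to the identity (up to clipping).
    """
    data = np.asarray(vol.data, dtype=float)
    ax_mm, lat_mm = p.psf_sigma
    sx, sy, _ = vol.spacing
    sig_vox = (lat_mm / sx, ax_mm / sy, 0.0)  # blur within frames only
    if any(s > 0 for s in sig_vox):
        pre_max = data.max()
        data = ndimage.gaussian_filter(data, sigma=sig_vox, mode="nearest")
        if p.normalize_gain:
            dmin, dmax = data.min(), data.max()
            if dmax > dmin and dmax < pre_max:
                data = dmin + (data - dmin) * (pre_max - dmin) / (dmax - dmin)
    rng = np.random.default_rng(seed)
    if p.multiplicative_sigma > 0:
        data = data * (1.0 + rng.normal(0.0, p.multiplicative_sigma, data.shape))
    if p.additive_sigma > 0:
        data = data + rng.normal(0.0, p.additive_sigma, data.shape)
    return vol.copy_with(np.clip(data, 0.0, 255.0))


def generate_wire_phantom(spec: WirePhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render the wire phantom and its exact ground truth.

    Wires are rasterized as bright tubes, anti-aliased by the fractional
    in-plane coverage of the wire cross-section; speckle is applied with
    the spec's seed.  The ground-truth directions are exact, so the
    angle between the two group directions equals
    ``spec.inter_group_angle`` to machine precision.
    """
    xs, ys, zs = _grid_coords(spec.extent_mm, spec.spacing)
    nx, ny, nz = len(xs), len(ys), len(zs)
    sx, sy, _ = spec.spacing
    origin = np.array([xs[0], ys[0], zs[0]])
    _, wire_i, water_i = spec.intensities
    data = np.full((nx, ny, nz), float(water_i))

    d_a, d_b = spec.group_directions()
    offs_a, offs_b = spec.wire_offsets()
    r = spec.wire_diameter / 2.0
    h = min(sx, sy)  # effective pixel width for coverage anti-aliasing
    margin = max(sx, sy)

    wire_idx = 0
    for offsets, d in ((offs_a, d_a), (offs_b, d_b)):
        tanx = d[0] / d[2]
        cosx = d[2] / np.hypot(d[0], d[2])
        for (x0, y0) in offsets:
            # wire track in the imaged extent: x(z) = x0 + z*tan
            x_ends = x0 + np.array([zs[0], zs[-1]]) * tanx
            if (np.any(x_ends < xs[0] + margin) or np.any(x_ends > xs[-1] - margin)
                    or y0 < ys[0] + margin or y0 > ys[-1] - margin):
                raise ValueError(f"wire {wire_idx} exits the volume extent")
            # perpendicular distance: in-plane xz part plus y offset
            dx = xs[:, None] - (x0 + zs[None, :] * tanx)   # (nx, nz)
            dxz = np.abs(dx) * cosx
            j_lo = int(np.searchsorted(ys, y0 - (r + 2 * sy)))
            j_hi = int(np.searchsorted(ys, y0 + (r + 2 * sy))) + 1
            for j in range(j_lo, min(j_hi, ny)):
                dist = np.hypot(dxz, ys[j] - y0)
                cover = np.clip((r + h / 2.0 - dist) / h, 0.0, 1.0)
                vals = water_i + (wire_i - water_i) * cover
                np.maximum(data[:, j, :], vals, out=data[:, j, :])
            wire_idx += 1

    clean = Volume(data, spec.spacing, origin)
    vol = add_speckle(clean, spec.noise, spec.seed)

    # compartment masks: y slabs around each group, padded by half a pitch.
    # The segmented region ends a margin short of the z faces, emulating a
    # segmentation interior to the reconstructed volume (wires run through
    # the faces of the imaged sub-region, but a real segmentation never
    # abuts the reconstruction boundary).
    z_ok = (zs >= zs[0] + spec.mask_z_margin_mm) & (zs <= zs[-1] - spec.mask_z_margin_mm)

    def slab(y_values: np.ndarray) -> MaskVolume:
        lo = y_values.min() - spec.hole_pitch / 2.0
        hi = y_values.max() + spec.hole_pitch / 2.0
        m = np.zeros((nx, ny, nz), dtype=bool)
        m[:, (ys >= lo) & (ys <= hi), :] = z_ok[None, :]
        return MaskVolume(m, spec.spacing, origin)

    mask_a = slab(offs_a[:, 1])
    mask_b = slab(offs_b[:, 1])
    if np.any(mask_a.data & mask_b.data):
        raise ValueError("wire group slabs overlap; increase group separation")

    truth = GroundTruth(
        directions={"A": d_a, "B": d_b},
        masks={"A": mask_a, "B": mask_b},
        inter_group_angle=float(folded_angle_deg(d_a, d_b)),
    )
    return vol, truth


def generate_pennate_muscle(spec: PennateMuscleSpec) -> tuple[Volume, GroundTruth]:
    """Render the two-compartment pennate muscle and its ground truth."""
    ax_, ay_, az_ = spec.semi_axes
    extent = (2 * ax_ + 2 * spec.margin_mm,
              2 * ay_ + 2 * spec.margin_mm,
              2 * az_ + 2 * spec.margin_mm)
    xs, ys, zs = _grid_coords(extent, spec.spacing)
    origin = np.array([xs[0], ys[0], zs[0]])
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    n = spec.envelope_exponent
    envelope = (np.abs(X / ax_) ** n + np.abs(Y / ay_) ** n + np.abs(Z / az_) ** n) <= 1.0
    if not envelope.any():
        raise ValueError("empty envelope")

    bg, tissue, line_i, apo_i = spec.intensities
    half_t = spec.apo_thickness / 2.0
    apo = envelope & (np.abs(Y) <= half_t)
    sup = envelope & (Y > half_t)
    deep = envelope & (Y < -half_t)
    if not sup.any() or not deep.any():
        raise ValueError("pennation geometry incompatible with envelope: "
                         "a compartment is empty")

    d_sup, d_deep = spec.compartment_directions()
    sigma_l = spec.line_width / 2.0
    data = np.full(envelope.shape, float(bg))
    data[envelope] = tissue

    for comp_mask, d in ((sup, d_sup), (deep, d_deep)):
        # orthonormal basis perpendicular to the line direction
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(d, e1)
        u = X + np.zeros_like(Y) + np.zeros_like(Z)           # = X broadcast
        v = Y * e2[1] + Z * e2[2]
        du = np.mod(u + spec.fascicle_pitch / 2, spec.fascicle_pitch) - spec.fascicle_pitch / 2
        dv = np.mod(v + spec.fascicle_pitch / 2, spec.fascicle_pitch) - spec.fascicle_pitch / 2
        rho2 = du ** 2 + dv ** 2
        lines = tissue + (line_i - tissue) * np.exp(-rho2 / (2 * sigma_l ** 2))
        data[comp_mask] = lines[comp_mask]

    data[apo] = apo_i
    clean = Volume(data, spec.spacing, origin)
    vol = add_speckle(clean, spec.noise, spec.seed)

    masks = {
        "muscle": MaskVolume(envelope, spec.spacing, origin),
        "superficial": MaskVolume(sup, spec.spacing, origin),
        "deep": MaskVolume(deep, spec.spacing, origin),
    }
    apo_mask = MaskVolume(apo, spec.spacing, origin)
    apo_dir = np.asarray(spec.apo_direction, dtype=float)
    apo_dir = apo_dir / np.linalg.norm(apo_dir)

    vectors = np.full(envelope.shape + (3,), np.nan)
    vectors[sup] = d_sup
    vectors[deep] = d_deep
    field = DirectionField(vectors, spec.spacing, origin)
    angle_map = np.full(envelope.shape, np.nan)
    angle_map[sup] = folded_angle_deg(d_sup, apo_dir)
    angle_map[deep] = folded_angle_deg(d_deep, apo_dir)

    truth = GroundTruth(
        directions={"superficial": d_sup, "deep": d_deep},
        masks=masks,
        direction_field=field,
        angle_map=angle_map,
        aponeurosis_mask=apo_mask,
        aponeurosis_direction=apo_dir,
    )
    return vol, truth
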
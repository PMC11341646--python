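"""Freehand 3D ultrasound reconstruction.

Turns a stack of pose-tracked 2D B-mode frames into a 3D
:class:`~penna3d.core.Volume`:

1. temporal alignment of the image stream against the position encoder
   by normalized cross-correlation;
2. a reconstruction grid whose axes come from a PCA of the world-space
   frame corner coordinates;
3. nearest-neighbor binning of frame pixels into voxels (collisions
   averaged) followed by a nearest-neighbor hole fill for empty voxels
   between filled ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Volume

__all__ = [
    "FrameStack",
    "PoseSequence",
    "VolumeGrid",
    "estimate_time_offset",
    "define_grid",
    "reconstruct",
]


@dataclass
class FrameStack:
    """Timed 2D intensity frames with a common pixel spacing (mm)."""

    frames: list[np.ndarray]
    pixel_spacing: tuple[float, float]
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if not self.frames:
            raise ValueError("frame stack is empty")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share the same dimensions")
        if any(f.ndim != 2 for f in self.frames):
            raise ValueError("frames must be 2D")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape  # type: ignore[return-value]

    def corner_coords_image(self) -> np.ndarray:
        """The 4 frame corners in image-plane mm, shape (4, 3), z=0."""
        nu, nv = self.frame_shape
        px, py = self.pixel_spacing
        umax, vmax = (nu - 1) * px, (nv - 1) * py
        return np.array(
            [[0.0, 0.0, 0.0], [umax, 0.0, 0.0], [0.0, vmax, 0.0], [umax, vmax, 0.0]]
        )


@dataclass
class PoseSequence:
    """Rigid transforms (image plane -> device coordinates, mm) over time."""

    rotations: np.ndarray  # (n, 3, 3)
    translations: np.ndarray  # (n, 3)
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        if self.rotations.shape != (n, 3, 3) or self.translations.shape != (n, 3):
            raise ValueError("rotations (n,3,3) and translations (n,3) required")
        eye = np.eye(3)
        for k, R in enumerate(self.rotations):
            if not np.allclose(R.T @ R, eye, atol=1e-8):
                raise ValueError(f"rotation {k} is not orthonormal")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def interpolate(self, times: np.ndarray) -> "PoseSequence":
        """Resample poses at the given times.

        Translation is linear; rotation matrices are interpolated
        entrywise and re-orthonormalized by polar projection (sweeps in
        this application are close to linear, so the small-angle linear
        interpolation is adequate).
        """
        times = np.asarray(times, dtype=float)
        t = self.timestamps
        trans = np.stack(
            [np.interp(times, t, self.translations[:, d]) for d in range(3)], axis=-1
        )
        rots = np.empty((len(times), 3, 3))
        for a in range(3):
            for b in range(3):
                rots[:, a, b] = np.interp(times, t, self.rotations[:, a, b])
        # project back to SO(3)
        for k in range(len(times)):
            u, _, vt = np.linalg.svd(rots[k])
            R = u @ vt
            if np.linalg.det(R) < 0:
                u[:, -1] *= -1
                R = u @ vt
            rots[k] = R
        return PoseSequence(rots, trans, np.arange(len(times), dtype=float))


@dataclass
class VolumeGrid:
    """Reconstruction grid: origin, orthonormal axes, spacing, dims."""

    origin: np.ndarray
    axes: np.ndarray
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-8):
            raise ValueError("grid axes must be orthonormal")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 in each direction")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points, shape (..., 3)."""
        local = (np.asarray(points, dtype=float) - self.origin) @ self.axes
        return local / np.asarray(self.spacing)


def estimate_time_offset(
    image_signal: np.ndarray, encoder_signal: np.ndarray, rate: float
) -> float:
    """Temporal offset between the image stream and the encoder stream.

    Both series are sampled at ``rate`` Hz (e.g. the vertical position of
    a tracked line in the image versus the encoder reading while the
    probe is moved up and down in a water bath).  The offset is the lag
    maximizing the normalized cross-correlation of the detrended
    signals, in seconds.  Positive values mean the image stream *lags*
    the encoder.
    """
    x = np.asarray(image_signal, dtype=float)
    y = np.asarray(encoder_signal, dtype=float)
    if x.size < 8 or y.size < 8:
        raise ValueError("signals must have at least 8 samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    # linear detrend to remove ramp/DC before correlating
    for arr in (x, y):
        n = arr.size
        t = np.arange(n)
        coef = np.polyfit(t, arr, 1)
        arr -= np.polyval(coef, t)
    if np.allclose(x, 0) or np.allclose(y, 0):
        raise ValueError("no signal variance after detrending")
    x = x / np.linalg.norm(x)
    y = y / np.linalg.norm(y)
    corr = np.correlate(x, y, mode="full")
    lag = int(np.argmax(corr)) - (y.size - 1)
    return lag / rate


def define_grid(
    stack: FrameStack,
    poses: PoseSequence,
    spacing: tuple[float, float, float],
) -> VolumeGrid:
    """Reconstruction grid from a PCA of the world-space frame corners.

    The grid axes are the principal axes of the 4*nframes corner point
    cloud, ordered by decreasing variance and sign-fixed against the
    image axes and the sweep direction; origin and dims are the tight
    bounding box of the corners in PCA space, expanded to whole voxels.
    """
    if len(stack.frames) < 2:
        raise ValueError("need at least 2 frames to define a grid")
    poses_f = poses.interpolate(stack.timestamps)
    corners_img = stack.corner_coords_image()
    corners = np.concatenate(
        [
            corners_img @ R.T + t
            for R, t in zip(poses_f.rotations, poses_f.translations)
        ]
    )
    center = corners.mean(axis=0)
    centered = corners - center
    cov = centered.T @ centered / len(corners)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, axes = evals[order], evecs[:, order]
    if evals[1] < 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate corner cloud: points are collinear")

    # sign convention: positive dot with the image axes / sweep direction
    sweep = poses_f.translations[-1] - poses_f.translations[0]
    refs = [
        poses_f.rotations[0][:, 0],  # image u axis in world
        poses_f.rotations[0][:, 1],  # image v axis in world
        sweep if np.linalg.norm(sweep) > 0 else np.array([0.0, 0.0, 1.0]),
    ]
    for i in range(3):
        dots = [abs(axes[:, i] @ r) for r in refs]
        ref = refs[int(np.argmax(dots))]
        d = axes[:, i] @ ref
        if abs(d) < 1e-12:
            d = axes[2, i]  # tie: orient toward +z
        if d < 0:
            axes[:, i] = -axes[:, i]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]

    proj = centered @ axes
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    spacing = tuple(float(s) for s in spacing)
    dims = tuple(int(np.ceil((h - l) / s)) + 1 for l, h, s in zip(lo, hi, spacing))
    origin = center + axes @ lo
    return VolumeGrid(origin, axes, spacing, dims)


def reconstruct(
    stack: FrameStack,
    poses: PoseSequence,
    grid: VolumeGrid,
    fill_radius: int = 3,
) -> Volume:
    """Bin frame pixels into the grid and fill interior holes.

    Pass 1 maps every frame pixel to its nearest voxel; voxels hit by
    several pixels take the arithmetic mean.  Pass 2 assigns each empty
    voxel the value of its nearest filled voxel (in index space) if that
    neighbor is within ``fill_radius`` voxels; voxels further away are
    considered outside the swept region and stay 0.

    The returned volume carries a boolean ``unreached`` attribute
    flagging voxels filled by neither pass.
    """
    if not stack.frames:
        raise ValueError("empty frame stack")
    poses_f = poses.interpolate(stack.timestamps)
    nu, nv = stack.frame_shape
    px, py = stack.pixel_spacing
    uu, vv = np.meshgrid(np.arange(nu) * px, np.arange(nv) * py, indexing="ij")
    plane = np.stack([uu.ravel(), vv.ravel(), np.zeros(uu.size)], axis=-1)

    dims = grid.dims
    sums = np.zeros(dims)
    counts = np.zeros(dims, dtype=np.int64)
    for frame, R, t in zip(stack.frames, poses_f.rotations, poses_f.translations):
        world = plane @ R.T + t
        idx = np.rint(grid.world_to_index(world)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(dims)), axis=1)
        if not ok.any():
            continue
        flat = np.ravel_multi_index(tuple(idx[ok].T), dims)
        np.add.at(sums.ravel(), flat, frame.ravel()[ok])
        np.add.at(counts.ravel(), flat, 1)
    filled = counts > 0
    if not filled.any():
        raise ValueError("no frame pixel landed in the reconstruction grid")
    data = np.zeros(dims)
    data[filled] = sums[filled] / counts[filled]

    # pass 2: nearest filled voxel within fill_radius (index space)
    dist, (ii, jj, kk) = ndimage.distance_transform_edt(
        ~filled, return_indices=True
    )
    fillable = (~filled) & (dist <= fill_radius)
    data[fillable] = data[ii[fillable], jj[fillable], kk[fillable]]

    vol = Volume(data, grid.spacing, grid.origin, grid.axes)
    vol.unreached = ~(filled | fillable)  # type: ignore[attr-defined]
    return vol
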
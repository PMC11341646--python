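"""Shared geometric containers for the fascicle-orientation pipeline.

Conventions used throughout the package:

* Array index order is ``(i, j, k)`` for the (x, y, z) voxel axes, i.e.
  ``data[i, j, k]`` and ``data.shape == (nx, ny, nz)``.
* World coordinates (mm) of a voxel index are given by one affine
  everywhere: ``world = origin + axes @ (index * spacing)``.
* Missing direction vectors are marked with NaN components; the zero
  vector is a legal (pre-normalization) direction and is *not* a missing
  marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "Volume",
    "MaskVolume",
    "DirectionField",
    "FrangiParams",
    "PruneParams",
    "SmoothParams",
    "PipelineConfig",
]

_ORTHO_TOL = 1e-9


def _check_axes(axes: np.ndarray) -> np.ndarray:
    axes = np.asarray(axes, dtype=float)
    if axes.shape != (3, 3):
        raise ValueError(f"axes must be 3x3, got {axes.shape}")
    if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-8):
        raise ValueError("axes must be orthonormal")
    return axes


@dataclass
class Volume:
    """A 3D scalar intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, conventionally on a 0-255 scale.
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm; all components positive.
    origin : ndarray, shape (3,)
        World position (mm) of voxel index ``(0, 0, 0)``.
    axes : ndarray, shape (3, 3)
        Orthonormal matrix whose *columns* are the world directions of
        the voxel axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = _check_axes(self.axes)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of integer or fractional voxel indices.

        ``indices`` has shape (..., 3); returns the same shape.
        """
        idx = np.asarray(indices, dtype=float)
        return self.origin + (idx * np.asarray(self.spacing)) @ self.axes.T

    def same_geometry(self, other: "Volume | MaskVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )

    def copy_with(self, data: np.ndarray) -> "Volume":
        """New Volume with the same geometry but different data."""
        return Volume(np.asarray(data), self.spacing, self.origin.copy(), self.axes.copy())


@dataclass
class MaskVolume:
    """Binary mask sharing geometry with an associated :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("mask data must be 3D")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = _check_axes(self.axes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    world_coords = Volume.world_coords
    same_geometry = Volume.same_geometry

    def copy_with(self, data: np.ndarray) -> "MaskVolume":
        return MaskVolume(np.asarray(data), self.spacing, self.origin.copy(), self.axes.copy())


class DirectionField:
    """A 3D grid of 3-component direction vectors.

    ``vectors`` has shape (nx, ny, nz, 3).  Voxels without a direction
    are marked by NaN in all three components ("missing"); every
    non-missing vector has finite components.
    """

    def __init__(
        self,
        vectors: np.ndarray,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        origin: np.ndarray | None = None,
        axes: np.ndarray | None = None,
    ) -> None:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 4 or vectors.shape[-1] != 3:
            raise ValueError(f"vectors must have shape (nx,ny,nz,3), got {vectors.shape}")
        self.vectors = vectors
        self.spacing = tuple(float(s) for s in spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float).reshape(3)
        self.axes = np.eye(3) if axes is None else _check_axes(axes)
        # reject half-missing vectors: a vector is either fully set or fully NaN
        finite = np.isfinite(vectors)
        partial = finite.any(axis=-1) & ~finite.all(axis=-1)
        if partial.any():
            raise ValueError("vectors must be fully finite or fully NaN per voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def support(self) -> np.ndarray:
        """Boolean grid, True where a direction is present."""
        return np.isfinite(self.vectors).all(axis=-1)

    def n_support(self) -> int:
        return int(self.support.sum())

    world_coords = Volume.world_coords

    @classmethod
    def empty(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        origin: np.ndarray | None = None,
        axes: np.ndarray | None = None,
    ) -> "DirectionField":
        v = np.full(shape + (3,), np.nan)
        return cls(v, spacing, origin, axes)

    def copy_with(self, vectors: np.ndarray) -> "DirectionField":
        return DirectionField(vectors, self.spacing, self.origin.copy(), self.axes.copy())

    def support_vectors(self) -> np.ndarray:
        """(n, 3) array of the non-missing vectors in index order."""
        return self.vectors[self.support]

    def same_geometry(self, other, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )


# ---------------------------------------------------------------------------
# configuration

@dataclass
class FrangiParams:
    """Vessel-enhancement filter settings.

    sigma is the Gaussian scale in *pixels* of the slice grid (2 for
    muscle data, 3.5 for phantom data); beta and c are the line/blob and
    structureness sensitivities of the vesselness measure.
    """

    sigma: float = 2.0
    beta: float = 0.5
    c: float = 15.0
    slice_plane: str = "yz"  # "yz" (muscle) or "xz" (phantom)

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.beta <= 0 or self.c <= 0:
            raise ValueError("sigma, beta and c must be positive")
        if self.slice_plane not in ("yz", "xz", "xy"):
            raise ValueError(f"unknown slice plane {self.slice_plane!r}")


@dataclass
class PruneParams:
    """Direction-field pruning cascade settings."""

    hessian_sigma: float = 2.0       # voxels, for the 3D Hessian
    binarize_fraction: float = 0.10  # of the maximum filtered value
    shrink_voxels: int = 10          # compartment-mask erosion iterations
    length_fraction: float = 0.50    # of the max spacing-scaled vector length
    min_neighbors: int = 18          # of the 26-neighborhood

    def __post_init__(self) -> None:
        if not 0 < self.binarize_fraction < 1:
            raise ValueError("binarize_fraction must be in (0,1)")
        if not 0 < self.length_fraction < 1:
            raise ValueError("length_fraction must be in (0,1)")
        if not 0 <= self.min_neighbors <= 26:
            raise ValueError("min_neighbors must be in [0,26]")
        if self.hessian_sigma <= 0:
            raise ValueError("hessian_sigma must be positive")
        if self.shrink_voxels < 0:
            raise ValueError("shrink_voxels must be >= 0")


@dataclass
class SmoothParams:
    """Penalized-least-squares smoother settings."""

    s_main: float = 35.0
    s_extrap: float = 0.5
    robust: bool = False
    max_iter: int = 100
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.s_main < 0 or self.s_extrap < 0:
            raise ValueError("smoothing parameters must be >= 0")


@dataclass
class PipelineConfig:
    """Full configuration of the fascicle-detection pipeline."""

    frangi: FrangiParams = field(default_factory=FrangiParams)
    prune: PruneParams = field(default_factory=PruneParams)
    smooth: SmoothParams = field(default_factory=SmoothParams)
    resample_n: int = 5000
    rng_seed: int = 0

    # convenience accessors mirrored from the sub-configs
    @property
    def hessian_sigma(self) -> float:
        return self.prune.hessian_sigma

    @classmethod
    def for_muscle(cls, **overrides) -> "PipelineConfig":
        cfg = cls(frangi=FrangiParams(sigma=2.0, slice_plane="yz"))
        return replace(cfg, **overrides)

    @classmethod
    def for_phantom(cls, **overrides) -> "PipelineConfig":
        # the wire phantom needs no epimysium guard, so no mask shrinking
        cfg = cls(
            frangi=FrangiParams(sigma=3.5, slice_plane="xz"),
            prune=PruneParams(shrink_voxels=0),
        )
        return replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return {
            "frangi": vars(self.frangi).copy(),
            "prune": vars(self.prune).copy(),
            "smooth": vars(self.smooth).copy(),
            "resample_n": self.resample_n,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            frangi=FrangiParams(**d.get("frangi", {})),
            prune=PruneParams(**d.get("prune", {})),
            smooth=SmoothParams(**d.get("smooth", {})),
            resample_n=int(d.get("resample_n", 5000)),
            rng_seed=int(d.get("rng_seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def unit(v: np.ndarray, axis: int = -1, eps: float = 0.0) -> np.ndarray:
    """Normalize vectors along ``axis``; zero-length raises if eps == 0."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if eps == 0.0 and np.any(n == 0):
        raise ValueError("cannot normalize zero-length vector")
    return v / np.maximum(n, eps if eps > 0 else 1)  # n>0 guaranteed when eps==0


def folded_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle between directions in degrees, folded to [0, 90].

    Directions are treated as axial (v and -v are equivalent):
    ``theta = arccos(|a.b| / (|a||b|))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-length vector in angle computation")
    cosang = np.abs(np.sum(a * b, axis=-1)) / (na * nb)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
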
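"""Reading and writing volumes, masks and vector fields.

Supported volume formats: MetaImage (``.mha``/``.mhd``), NIfTI
(``.nii``/``.nii.gz``) and TIFF slice stacks with a YAML spacing
sidecar.  Direction fields are exported as legacy ASCII VTK polydata
(POINTS + VECTORS), one point per non-missing voxel, positions in mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
import nibabel as nib
import tifffile
import yaml

from .core import DirectionField, MaskVolume, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_vector_field",
    "read_vector_field",
]

_MHA_EXT = (".mha", ".mhd")
_NII_EXT = (".nii", ".nii.gz")
_TIFF_EXT = (".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _rescale_to_255(data: np.ndarray) -> tuple[np.ndarray, float]:
    """Linearly rescale intensities to 0-255 if the source range is wider.

    Returns the (possibly) rescaled data and the multiplicative factor
    applied, so the original scale can be recovered losslessly.
    """
    data = np.asarray(data, dtype=float)
    dmax = float(data.max()) if data.size else 0.0
    if dmax > 255.0:
        factor = 255.0 / dmax
        return data * factor, factor
    return data, 1.0


def read_volume(path: str | Path) -> Volume:
    """Read a 3D volume from MHA, NIfTI or a TIFF stack.

    Intensities wider than the 0-255 scale are rescaled linearly on
    load; the applied factor is recorded on the returned object as
    ``intensity_scale`` (1.0 when no rescale happened).

    TIFF stacks require a sidecar ``<stem>.yaml`` next to the file with
    at least a ``spacing: [sx, sy, sz]`` entry (mm); ``origin`` is
    optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    ext = _suffix(path)
    if ext in _MHA_EXT:
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D image, got {img.GetDimension()}D: {path}")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
        spacing = img.GetSpacing()
        origin = np.array(img.GetOrigin())
        axes = np.array(img.GetDirection()).reshape(3, 3)
    elif ext in _NII_EXT:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D image, got ndim={data.ndim}: {path}")
        aff = img.affine
        lin = aff[:3, :3]
        spacing = tuple(np.linalg.norm(lin, axis=0))
        if any(s == 0 for s in spacing):
            raise ValueError(f"degenerate affine in {path}: zero-length axis")
        axes = lin / np.asarray(spacing)
        origin = aff[:3, 3].copy()
    elif ext in _TIFF_EXT:
        stack = tifffile.imread(str(path))
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF payload, got ndim={stack.ndim}")
        data = stack.transpose(2, 1, 0)  # (slice,y,x) -> (x,y,slice)
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise ValueError(
                f"TIFF stack {path} has no spacing metadata: sidecar {sidecar.name} missing"
            )
        meta = yaml.safe_load(sidecar.read_text()) or {}
        if "spacing" not in meta:
            raise ValueError(f"sidecar {sidecar} is missing the 'spacing' field")
        spacing = tuple(float(s) for s in meta["spacing"])
        origin = np.asarray(meta.get("origin", (0.0, 0.0, 0.0)), dtype=float)
        axes = np.asarray(meta.get("axes", np.eye(3)), dtype=float).reshape(3, 3)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")

    data, factor = _rescale_to_255(np.asarray(data, dtype=float))
    vol = Volume(data, spacing, origin, axes)
    vol.intensity_scale = factor  # type: ignore[attr-defined]
    return vol


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume to MHA or NIfTI, preserving geometry."""
    path = Path(path)
    ext = _suffix(path)
    if ext in _MHA_EXT:
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        img.SetDirection(tuple(vol.axes.ravel()))
        sitk.WriteImage(img, str(path))
    elif ext in _NII_EXT:
        aff = np.eye(4)
        aff[:3, :3] = vol.axes * np.asarray(vol.spacing)
        aff[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), aff), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_mask(path: str | Path) -> MaskVolume:
    vol = read_volume(path)
    return MaskVolume(vol.data > 0.5, vol.spacing, vol.origin, vol.axes)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    write_volume(
        Volume(mask.data.astype(np.uint8), mask.spacing, mask.origin, mask.axes), path
    )


def write_vector_field(field: DirectionField, path: str | Path) -> None:
    """Export a direction field as legacy ASCII VTK polydata.

    One point per non-missing voxel; positions are world coordinates in
    mm (``origin + axes @ (index * spacing)``) with a 3-component
    ``direction`` vector attribute.  Missing voxels are omitted.
    """
    support = field.support
    n = int(support.sum())
    if n == 0:
        raise ValueError("empty field: no non-missing voxels to export")
    idx = np.argwhere(support)
    points = field.world_coords(idx)
    vectors = field.vectors[support]

    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("penna3d fascicle direction field\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, points, fmt="%.6f")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("VECTORS direction float\n")
        np.savetxt(fh, vectors, fmt="%.6f")


def read_vector_field(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a legacy-VTK point/vector export.

    Returns ``(points, vectors)`` as (n, 3) arrays; mainly for
    round-trip checking and downstream scripting, not a general VTK
    reader.
    """
    lines = Path(path).read_text().splitlines()
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n = int(lines[i].split()[1])
    points = np.loadtxt(lines[i + 1 : i + 1 + n]).reshape(n, 3)
    j = next(k for k, ln in enumerate(lines) if ln.startswith("VECTORS"))
    vectors = np.loadtxt(lines[j + 1 : j + 1 + n]).reshape(n, 3)
    return points, vectors
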
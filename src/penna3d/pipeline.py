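"""End-to-end fascicle-detection drivers.

``detect_fascicles`` chains the per-compartment stages (masked
vessel enhancement, 3D Hessian directions, pruning cascade, vector
smoothing) and is shared by the phantom and muscle workflows.  For
efficiency the work happens on the compartment's bounding box plus a
filter margin; the result is re-embedded into the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .core import DirectionField, MaskVolume, PipelineConfig, Volume
from .directions import (
    direction_field,
    fascicle_mask,
    fill_muscle,
    muscle_frame,
    prune_endpoints,
    rotate_mask,
    rotate_volume,
    scale_and_prune_lengths,
    smooth_field,
)
from .metrics import (
    PennationResult,
    PhantomAngleStats,
    aponeurosis_direction,
    compartment_summary,
    pennation_angles,
    phantom_angles,
)
from .synth import GroundTruth
from .vesselness import apply_mvef

__all__ = ["detect_fascicles", "run_phantom", "run_muscle", "MuscleRun"]


def _crop_slices(mask: np.ndarray, margin: int, shape) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def detect_fascicles(
    vol: Volume,
    compartment: MaskVolume,
    apo_mask: MaskVolume | None,
    config: PipelineConfig,
    long_axis=(0.0, 0.0, 1.0),
) -> DirectionField:
    """Direction field at the detected fascicle positions of one compartment.

    Runs the full detection chain: aponeurosis zeroing and compartment
    masking, slice-wise vessel enhancement, 3D Hessian eigenanalysis,
    binarization at a fraction of the filtered maximum, compartment
    shrinking, voxel-size scaling with length pruning, end-point
    removal, and penalized-least-squares smoothing of the surviving
    vectors.  The returned field is non-missing exactly at the surviving
    detected voxels.
    """
    if compartment.count() == 0:
        raise ValueError("empty compartment mask")
    margin = int(np.ceil(4 * max(config.frangi.sigma, config.prune.hessian_sigma)))
    sl = _crop_slices(compartment.data, margin, vol.shape)
    sub_origin = vol.world_coords(np.array([s.start for s in sl], dtype=float))
    vol_c = Volume(vol.data[sl], vol.spacing, sub_origin, vol.axes)
    comp_c = MaskVolume(compartment.data[sl], vol.spacing, sub_origin, vol.axes)
    apo_c = None
    if apo_mask is not None:
        apo_c = MaskVolume(apo_mask.data[sl], vol.spacing, sub_origin, vol.axes)

    filtered = apply_mvef(vol_c, comp_c, apo_c, config.frangi)
    fmask = fascicle_mask(filtered, comp_c, config.prune)
    if fmask.count() == 0:
        raise ValueError("no voxels survive binarization and shrinking")
    raw = direction_field(
        filtered, config.prune.hessian_sigma, support=fmask.data, long_axis=long_axis
    )
    scaled = scale_and_prune_lengths(
        raw, fmask, vol.spacing, config.prune.length_fraction
    )
    pruned = prune_endpoints(scaled, config.prune.min_neighbors)
    if pruned.n_support() == 0:
        raise ValueError("no voxels survive end-point pruning")
    # smooth on the support bounding box: only values at the detected
    # positions are kept, so the surrounding all-missing margin is inert
    sl2 = _crop_slices(pruned.support, 2, pruned.shape)
    sub2 = DirectionField(pruned.vectors[sl2], pruned.spacing,
                          pruned.world_coords(np.array([s.start for s in sl2],
                                                       dtype=float)), pruned.axes)
    smoothed = smooth_field(
        sub2, config.smooth.s_main, robust=config.smooth.robust,
        max_iter=config.smooth.max_iter, tol=config.smooth.tol,
    )
    # keep the smoothed vectors at the detected positions only
    keep = pruned.support
    vecs = np.full_like(pruned.vectors, np.nan)
    sm_full = np.full_like(pruned.vectors, np.nan)
    sm_full[sl2] = smoothed.vectors
    norms = np.linalg.norm(sm_full[keep], axis=1, keepdims=True)
    vecs[keep] = sm_full[keep] / norms

    out = np.full(vol.shape + (3,), np.nan)
    out[sl] = vecs
    return DirectionField(out, vol.spacing, vol.origin, vol.axes)


def run_phantom(
    vol: Volume,
    truth: GroundTruth,
    config: PipelineConfig | None = None,
) -> tuple[PhantomAngleStats, DirectionField, DirectionField]:
    """Phantom workflow: detect both wire groups and compare their angles.

    Returns the pairwise angle statistics against the ground-truth
    inter-group angle together with the two detected direction fields.
    """
    config = config or PipelineConfig.for_phantom()
    field_a = detect_fascicles(vol, truth.masks["A"], None, config)
    field_b = detect_fascicles(vol, truth.masks["B"], None, config)
    stats = phantom_angles(
        field_a, field_b, truth.inter_group_angle, seed=config.rng_seed
    )
    return stats, field_a, field_b


@dataclass
class MuscleRun:
    """Outputs of the muscle workflow, all in the muscle frame."""

    pennation: PennationResult
    fields: dict[str, DirectionField]
    filled: dict[str, DirectionField]
    masks: dict[str, MaskVolume]
    volume: Volume


def run_muscle(
    vol: Volume,
    muscle_mask: MaskVolume,
    compartments: dict[str, MaskVolume],
    apo_mask: MaskVolume,
    config: PipelineConfig | None = None,
    rotate: bool = True,
) -> MuscleRun:
    """Muscle workflow: rotate, detect per compartment, fill, pennate.

    Rotates volume and masks into the muscle principal-axis frame (PCA
    of the whole-muscle mask), detects directions per compartment with
    the aponeurosis zeroed, extrapolates each compartment's field over
    its full (rotated) mask, and computes per-voxel pennation angles
    against the aponeurosis PCA direction with resampled summaries.
    """
    config = config or PipelineConfig.for_muscle()
    if rotate:
        frame = muscle_frame(muscle_mask)
        vol_r = rotate_volume(vol, frame)
        muscle_r = rotate_mask(muscle_mask, frame)
        comps_r = {k: rotate_mask(m, frame) for k, m in compartments.items()}
        apo_r = rotate_mask(apo_mask, frame)
    else:
        vol_r, muscle_r, comps_r, apo_r = vol, muscle_mask, compartments, apo_mask

    apo_dir = aponeurosis_direction(apo_r)
    fields: dict[str, DirectionField] = {}
    filled: dict[str, DirectionField] = {}
    combined = np.full(vol_r.shape + (3,), np.nan)
    for name, comp in comps_r.items():
        f = detect_fascicles(vol_r, comp, apo_r, config, long_axis=apo_dir)
        fields[name] = f
        ff = fill_muscle(f, comp, config.smooth)
        filled[name] = ff
        sel = comp.data
        combined[sel] = ff.vectors[sel]
    combined_field = DirectionField(combined, vol_r.spacing, vol_r.origin, vol_r.axes)

    angles = pennation_angles(combined_field, apo_dir)
    summaries = {
        name: compartment_summary(angles, comp, n=config.resample_n,
                                  seed=config.rng_seed)
        for name, comp in comps_r.items()
    }
    pennation = PennationResult(angles, apo_dir, summaries)
    masks = {"muscle": muscle_r, "aponeurosis": apo_r, **comps_r}
    return MuscleRun(pennation, fields, filled, masks, vol_r)
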
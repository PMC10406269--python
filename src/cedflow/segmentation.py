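"""Semi-automated lesion segmentation: speed image, seed bubbles, region growth.

The procedure mirrors the interactive active-contour workflow used to
delineate pontine lesions on T2W images and ADC maps: a dual-threshold
*speed image* (lower threshold near the normal-appearing-white-matter level,
upper near the CSF level) gates a seeded region evolution started from
spherical "bubbles", with a curvature-regularizing morphological smoothing
whose cadence is set by a smoothing weight.  The evolution is a
morphological stand-in for a level-set active contour: one 6-connected
dilation per step restricted to admissible voxels (speed > 0.5), followed by
a closing pass that fills front concavities, with the result restricted to
the connected component containing the seeds.  Closing never removes an
admitted voxel, so on a noise-free scene the evolution converges to exactly
the admissible connected component — volumes are then exact up to
voxelization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import ImageGrid, VolumeImage

__all__ = [
    "SegmentationParams",
    "LesionMask",
    "build_speed_image",
    "segment_lesion",
    "mask_stats",
    "auto_params",
]

_STRUCT = ndimage.generate_binary_structure(3, 1)   # 6-connectivity


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds, seeds and evolution settings for one segmentation.

    ``seeds`` is a list of ``(world_point_mm, radius_mm)`` bubbles.  The
    smoothing weight maps to the cadence of the smoothing pass: below 0.25
    never, 0.25-0.75 every second growth step, above 0.75 every step (the
    default 0.8 smooths every step).
    """

    lower_threshold: float
    upper_threshold: float
    seeds: list = field(default_factory=list)
    smoothing_weight: float = 0.8
    max_iterations: int = 500
    convergence_fraction: float = 0.0

    def __post_init__(self):
        if not self.lower_threshold < self.upper_threshold:
            raise ValueError("lower_threshold must be below upper_threshold")
        if not 0.0 <= self.smoothing_weight <= 1.0:
            raise ValueError("smoothing_weight must lie in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")

    @property
    def smoothing_every(self) -> int:
        """Growth steps between smoothing passes (0 = never)."""
        if self.smoothing_weight < 0.25:
            return 0
        if self.smoothing_weight <= 0.75:
            return 2
        return 1


@dataclass(frozen=True)
class LesionMask:
    """A binary lesion region with its volumetry and intensity statistics.

    ``volume_ml`` is exactly ``voxel_count * voxel volume (mm^3) / 1000``;
    intensity statistics are the mean and sample (n-1) SD over the mask on
    the stated reference image.
    """

    grid: ImageGrid
    mask: np.ndarray
    voxel_count: int
    volume_ml: float
    intensity_mean: float
    intensity_sd: float
    reference_modality: str
    leaked: bool = False

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        object.__setattr__(self, "mask", mask)


def build_speed_image(v: VolumeImage, params: SegmentationParams) -> VolumeImage:
    """Dual-threshold speed image in [0, 1].

    Speed is 1 strictly inside the admissible intensity band, 0 at and
    beyond both thresholds, with a linear ramp of width 5% of the threshold
    gap just inside each threshold.
    """
    lo, hi = params.lower_threshold, params.upper_threshold
    vmin, vmax = float(v.values.min()), float(v.values.max())
    if lo > vmax or hi < vmin:
        warnings.warn(
            f"thresholds ({lo}, {hi}) lie outside the image intensity "
            f"range ({vmin:.3g}, {vmax:.3g})", stacklevel=2)
    w = 0.05 * (hi - lo)
    ramp_up = (v.values - lo) / w
    ramp_down = (hi - v.values) / w
    speed = np.clip(np.minimum(np.minimum(ramp_up, ramp_down), 1.0), 0.0, 1.0)
    return v.with_values(speed)


def _seed_mask(grid: ImageGrid, seeds) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    world = None
    for point, radius in seeds:
        idx = grid.world_to_index(np.asarray(point, dtype=float))[0]
        if np.any(idx < 0) or np.any(idx > np.asarray(grid.shape) - 1):
            continue
        if radius <= 0:
            mask[tuple(np.round(idx).astype(int))] = True
            continue
        if world is None:
            world = grid.world_coordinates()
        d = np.linalg.norm(world - np.asarray(point, dtype=float), axis=-1)
        mask |= d <= radius
    return mask


def segment_lesion(v: VolumeImage, params: SegmentationParams,
                   speed: VolumeImage | None = None) -> LesionMask:
    """Grow seed bubbles through the speed image until the front stalls.

    Returns the connected region containing the seeds, with voxel count,
    volume and intensity statistics taken from ``v``.  Raises if no seed
    voxel is admissible; flags (does not raise) if the evolution reaches
    the image border, the signature of a leak through the band.
    """
    if speed is None:
        speed = build_speed_image(v, params)
    admissible = speed.values > 0.5
    if v.valid_mask is not None:
        admissible &= v.valid_mask

    seeds = _seed_mask(v.grid, params.seeds)
    region = seeds & admissible
    if not region.any():
        raise ValueError("no admissible seed: every seed bubble lies outside the speed band")

    every = params.smoothing_every
    for it in range(params.max_iterations):
        prev = int(region.sum())
        grown = ndimage.binary_dilation(region, structure=_STRUCT) & admissible
        if every and (it + 1) % every == 0:
            grown = (ndimage.binary_closing(grown, structure=_STRUCT) & admissible) | grown
        labels, _ = ndimage.label(grown, structure=_STRUCT)
        keep = np.unique(labels[region])
        keep = keep[keep > 0]
        region = np.isin(labels, keep)
        added = int(region.sum()) - prev
        if added <= params.convergence_fraction * max(region.sum(), 1):
            break

    border = np.zeros_like(region)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    leaked = bool((region & border).any())
    if leaked:
        warnings.warn("segmentation reached the image border (possible leak)", stacklevel=2)

    return _finalize(region, v, leaked)


def _finalize(region: np.ndarray, reference: VolumeImage, leaked: bool) -> LesionMask:
    count = int(region.sum())
    vals = reference.values[region]
    if reference.valid_mask is not None:
        vals = reference.values[region & reference.valid_mask]
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return LesionMask(
        grid=reference.grid,
        mask=region,
        voxel_count=count,
        volume_ml=count * reference.grid.voxel_volume_mm3 / 1000.0,
        intensity_mean=mean,
        intensity_sd=sd,
        reference_modality=reference.modality,
        leaked=leaked,
    )


def mask_stats(mask: LesionMask, reference: VolumeImage) -> LesionMask:
    """Recompute intensity mean/SD of a mask over another reference image.

    Volume fields are untouched; the two must share a grid.
    """
    if not mask.grid.same_geometry(reference.grid):
        raise ValueError("mask and reference image are on different grids")
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    sel = mask.mask
    if reference.valid_mask is not None:
        sel = sel & reference.valid_mask
    vals = reference.values[sel]
    if vals.size == 0:
        raise ValueError("empty mask after validity restriction")
    return replace(
        mask,
        intensity_mean=float(vals.mean()),
        intensity_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        reference_modality=reference.modality,
    )


def auto_params(v: VolumeImage, nawm_mask: np.ndarray, seed_point_mm,
                seed_radius_mm: float = 3.0, csf_percentile: float = 99.8,
                **kwargs) -> SegmentationParams:
    """Derive thresholds from reference regions instead of hand-typed numbers.

    The interactive workflow sets the lower threshold "approximately" at the
    NAWM level and the upper "approximately" at the CSF level, then adjusts
    both until the contour sits on the lesion edge.  The automated surrogate
    uses the partial-volume-unbiased midpoint rule: with a lesion sample
    taken around the seed point,

    * lower = (NAWM mean + lesion mean) / 2
    * upper = (lesion mean + CSF estimate) / 2

    where the CSF level is estimated as a high percentile of the image
    (CSF is the brightest tissue on both T2W and ADC).  A threshold midway
    between two tissue levels crosses a blurred edge at its half-way point,
    which places the segmented boundary on the true interface.
    """
    nawm_mask = np.asarray(nawm_mask, dtype=bool)
    if not nawm_mask.any():
        raise ValueError("empty NAWM reference mask")
    nawm_level = float(v.values[nawm_mask].mean())
    lesion_level = float(v.values[_seed_mask(v.grid, [(seed_point_mm, seed_radius_mm)])].mean())
    csf_level = float(np.percentile(v.values, csf_percentile))
    if not nawm_level < lesion_level:
        raise ValueError("lesion seed region is not brighter than NAWM; cannot set thresholds")
    lower = 0.5 * (nawm_level + lesion_level)
    upper = 0.5 * (lesion_level + max(csf_level, lesion_level * 1.2))
    return SegmentationParams(
        lower_threshold=lower,
        upper_threshold=upper,
        seeds=[(tuple(seed_point_mm), seed_radius_mm)],
        **kwargs,
    )
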
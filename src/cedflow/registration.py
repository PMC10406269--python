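"""Rigid registration, composed alignment of ADC maps, and subtraction maps.

The alignment chain mirrors the longitudinal protocol: linear registration
of ADC to T1W within each session and of T1W to T1W between sessions, with
the combined transform applied once to the post-infusion ADC map, which is
then subtracted voxel-by-voxel from the pre-infusion map.  Voxels whose ADC
rose above a noise floor form the bright region of the subtraction image —
the presumed infusate distribution.

Registration is rigid (6 DOF): between-session brainstem change is the
signal of interest and any scaling freedom would absorb part of it.
Cross-modality stages use Mattes mutual information, the same-modality
inter-session stage uses mean squares.  Metric sampling uses a regular
grid stride with a fixed seed, so the estimate is deterministic for fixed
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .imaging import ImageGrid, VolumeImage, resample
from .transforms import RigidTransform, compose

__all__ = [
    "register_rigid",
    "align_post_adc",
    "subtract_adc",
    "SubtractionMap",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    """Raised when a registration stage fails; carries the stage name."""


def _to_sitk(v: VolumeImage) -> sitk.Image:
    # SimpleITK indexes (x, y, z); GetImageFromArray takes (z, y, x).
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.values.transpose(2, 1, 0)))
    spacing = v.grid.voxel_size
    direction = v.grid.affine[:3, :3] / spacing[np.newaxis, :]
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(tuple(float(d) for d in direction.ravel()))
    img.SetOrigin(tuple(float(o) for o in v.grid.affine[:3, 3]))
    return img


def _from_euler(tx: sitk.Euler3DTransform) -> RigidTransform:
    rot = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    center = np.asarray(tx.GetCenter(), dtype=float)
    trans = np.asarray(tx.GetTranslation(), dtype=float)
    matrix = np.eye(4)
    matrix[:3, :3] = rot
    matrix[:3, 3] = center + trans - rot @ center
    return RigidTransform.from_matrix(matrix)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    metric: str = "mutual_information",
    levels: int = 3,
    sampling_percentage: float = 0.25,
) -> RigidTransform:
    """Estimate the rigid transform mapping fixed-world to moving-world.

    Multi-resolution (``levels`` pyramid levels, coarse to fine) regular-step
    gradient descent on the chosen metric over a regular (grid-strided,
    fixed-seed — hence deterministic) sample of the fixed image;
    ``sampling_percentage=1`` selects dense evaluation.  The returned
    transform is the resampling transform: feeding it to
    :func:`cedflow.imaging.resample` pulls ``moving`` onto ``fixed``'s grid.
    """
    if metric not in ("mutual_information", "mean_squares"):
        raise ValueError(f"unknown metric {metric!r}")
    if levels < 1:
        raise ValueError("levels must be >= 1")

    f = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat64)
    m = sitk.Cast(_to_sitk(moving), sitk.sitkFloat64)

    reg = sitk.ImageRegistrationMethod()
    if metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        reg.SetMetricAsMeanSquares()
    if sampling_percentage >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling_percentage, seed=1234)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()

    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    sigmas = [max(s / 2.0, 0.0) if s > 1 else 0.0 for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg.SetInitialTransform(initial, inPlace=True)

    try:
        result = reg.Execute(f, m)
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise RegistrationError(f"optimizer failed: {exc}") from exc
    stop = reg.GetOptimizerStopConditionDescription()
    if "overlap" in stop.lower():
        raise RegistrationError(f"no overlap between images: {stop}")
    return _from_euler(sitk.Euler3DTransform(result))


def align_post_adc(
    adc_pre: VolumeImage,
    t1_pre: VolumeImage,
    adc_post: VolumeImage,
    t1_post: VolumeImage,
    levels: int = 3,
    return_transforms: bool = False,
):
    """Map the post-infusion ADC onto the pre-infusion ADC grid.

    Three rigid stages are estimated — ADC(post) to T1W(post) and
    T1W(pre) to ADC(pre) within their sessions (mutual information), and
    T1W(post) to T1W(pre) between sessions (mean squares) — composed into a
    single transform, and applied once to the post ADC with trilinear
    interpolation.  A failing stage raises :class:`RegistrationError`
    naming the stage.
    """
    stages = {}
    for name, (mov, fix, metric) in {
        "adc_post->t1_post": (adc_post, t1_post, "mutual_information"),
        "t1_post->t1_pre": (t1_post, t1_pre, "mean_squares"),
        "t1_pre->adc_pre": (t1_pre, adc_pre, "mutual_information"),
    }.items():
        try:
            stages[name] = register_rigid(mov, fix, metric=metric, levels=levels)
        except RegistrationError as exc:
            raise RegistrationError(f"stage {name} failed: {exc}") from exc

    # Resampling transforms chain world frames: adc_pre -> t1_pre -> t1_post
    # -> adc_post; composing in that order gives the single pull-back map.
    net = compose(stages["adc_post->t1_post"],
                  compose(stages["t1_post->t1_pre"], stages["t1_pre->adc_pre"]))
    aligned = resample(adc_post, adc_pre.grid, net, interpolation="trilinear")
    if return_transforms:
        return aligned, {**stages, "combined": net}
    return aligned


@dataclass(frozen=True)
class SubtractionMap:
    """Voxelwise post-minus-pre ADC difference on the pre-infusion grid.

    ``positive_mask`` marks valid voxels whose ADC rose by more than the
    noise floor ``tau``; its volume is the subtraction-based estimate of the
    infusate distribution.  ``vd_ml`` refines that volume with a
    partial-volume correction: the count of voxels above half the plateau
    difference, which places the boundary at the half-height of the blurred
    difference profile.
    """

    grid: ImageGrid
    difference: np.ndarray
    validity_mask: np.ndarray
    tau: float
    positive_mask: np.ndarray
    plateau: float
    vd_ml: float

    @property
    def positive_volume_ml(self) -> float:
        return float(self.positive_mask.sum()) * self.grid.voxel_volume_mm3 / 1000.0


def subtract_adc(
    adc_pre: VolumeImage,
    adc_post_aligned: VolumeImage,
    tau: float | None = None,
    nawm_mask: np.ndarray | None = None,
    analysis_mask: np.ndarray | None = None,
) -> SubtractionMap:
    """Pre-from-post ADC subtraction with a noise-floored positive mask.

    ``tau`` (1e-6 mm^2/s) is the noise floor; when omitted it is set to
    3x the SD of the difference inside the NAWM reference mask, where no
    infusate-driven change is expected.  Statistics exclude voxels either
    session did not observe; ``analysis_mask`` (typically brain parenchyma:
    outside it — air background, CSF — the ADC map is noise-dominated and
    a difference carries no infusate signal) further restricts the
    validity region when given.
    """
    if not adc_pre.grid.same_geometry(adc_post_aligned.grid):
        raise ValueError("subtraction requires a shared grid")
    difference = adc_post_aligned.values - adc_pre.values
    validity = np.ones(adc_pre.grid.shape, dtype=bool)
    if adc_pre.valid_mask is not None:
        validity &= adc_pre.valid_mask
    if adc_post_aligned.valid_mask is not None:
        validity &= adc_post_aligned.valid_mask
    if analysis_mask is not None:
        validity &= np.asarray(analysis_mask, dtype=bool)

    if tau is None:
        if nawm_mask is None:
            raise ValueError("tau='auto' requires an NAWM reference mask")
        ref = difference[np.asarray(nawm_mask, dtype=bool) & validity]
        if ref.size < 2:
            raise ValueError("NAWM reference mask too small to estimate the noise floor")
        tau = 3.0 * float(ref.std(ddof=1))

    positive = (difference > tau) & validity
    if positive.any():
        plateau = float(np.median(difference[positive]))
        refined = (difference > max(tau, 0.5 * plateau)) & validity
        vd_ml = float(refined.sum()) * adc_pre.grid.voxel_volume_mm3 / 1000.0
    else:
        plateau = 0.0
        vd_ml = 0.0
    return SubtractionMap(
        grid=adc_pre.grid,
        difference=difference,
        validity_mask=validity,
        tau=float(tau),
        positive_mask=positive,
        plateau=plateau,
        vd_ml=vd_ml,
    )
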
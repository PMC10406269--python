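"""Volumetric image container, NIfTI I/O, grid resampling and ADC computation.

Conventions
-----------
* World frame is RAS in millimetres; voxel indices are 0-based and grids are
  defined at voxel centres, so the NIfTI affine maps index ``(i, j, k)`` to
  the centre of that voxel.
* ADC maps are carried in units of 1e-6 mm^2/s, the scale on which normal
  white matter sits near 700-900 and pontine tumors near 1000-1900.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .transforms import RigidTransform

__all__ = [
    "ImageGrid",
    "VolumeImage",
    "MODALITIES",
    "read_volume",
    "write_volume",
    "resample",
    "compute_adc",
]

MODALITIES = ("T1W", "T2W", "FLAIR", "DWI_b0", "DWI_b1000", "ADC")


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D sampling grid: shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size_from(affine) <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @staticmethod
    def voxel_size_from(affine: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel spacing (mm)."""
        return self.voxel_size_from(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel: |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float = 1.0, centered: bool = True) -> "ImageGrid":
        """Axis-aligned grid; by default the world origin sits at the volume centre."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        if centered:
            affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size_mm
        return cls(shape, affine)

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre world coordinates."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1).reshape(-1, 3)
        return self.index_to_world(ijk).reshape(self.shape + (3,))

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar image on a grid, tagged with its MRI modality.

    ``valid_mask`` marks voxels that carry observed data; it is introduced by
    resampling (out-of-domain fill) and by ADC computation (non-positive DWI
    signal) and is propagated into downstream statistics.
    """

    grid: ImageGrid
    values: np.ndarray
    modality: str
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"not a 3D volume: ndim={values.ndim}")
        if values.shape != self.grid.shape:
            raise ValueError(f"value shape {values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite voxels")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.modality == "ADC" and values.min() < 0:
            raise ValueError("ADC volume contains negative values")
        object.__setattr__(self, "values", values)
        if self.valid_mask is not None:
            vm = np.asarray(self.valid_mask, dtype=bool)
            if vm.shape != values.shape:
                raise ValueError("valid_mask shape mismatch")
            object.__setattr__(self, "valid_mask", vm)

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "VolumeImage":
        return VolumeImage(self.grid, values, modality or self.modality, self.valid_mask)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path, modality: str | None = None) -> VolumeImage:
    """Load a 3D NIfTI-1 volume.

    The modality tag is taken from an optional JSON sidecar (same stem,
    ``.json``) unless given explicitly; it defaults to ``T2W``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"not a 3D volume: {path} has shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {path}")
    if modality is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            modality = json.loads(sidecar.read_text()).get("modality", "T2W")
        else:
            modality = "T2W"
    grid = ImageGrid(data.shape, img.affine)
    return VolumeImage(grid, data, modality)


def write_volume(v: VolumeImage, path, sidecar: dict | None = None) -> None:
    """Write a volume as 32-bit float NIfTI-1 plus a JSON sidecar.

    The sidecar always records the modality tag; extra keys (session label,
    b-value, infused volume) may be supplied.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(v.values.astype(np.float32), v.grid.affine)
    nib.save(img, str(path))
    meta = {"modality": v.modality}
    if sidecar:
        meta.update(sidecar)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def resample(
    v: VolumeImage,
    target: ImageGrid,
    transform: RigidTransform | None = None,
    interpolation: str = "trilinear",
    fill_value: float = 0.0,
) -> VolumeImage:
    """Resample ``v`` onto ``target``.

    ``transform`` maps target-grid world coordinates into the source
    (``v``) world frame; identity when omitted.  Voxels whose source
    location falls outside the source domain are filled with
    ``fill_value`` and excluded from the returned ``valid_mask``.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    transform = transform or RigidTransform.identity()

    world = target.world_coordinates().reshape(-1, 3)
    src_world = transform.apply(world)
    src_idx = v.grid.world_to_index(src_world)

    shape = np.asarray(v.grid.shape, dtype=float)
    eps = 1e-9
    inside = np.all((src_idx >= -eps) & (src_idx <= shape - 1 + eps), axis=1)

    coords = src_idx.T.reshape(3, *target.shape)
    out = ndimage.map_coordinates(v.values, coords, order=order, mode="nearest")
    out = out.reshape(target.shape)
    valid = inside.reshape(target.shape)
    out[~valid] = fill_value

    if v.valid_mask is not None:
        src_valid = ndimage.map_coordinates(
            v.valid_mask.astype(np.float64), coords, order=0, mode="constant", cval=0.0
        ).reshape(target.shape).astype(bool)
        valid = valid & src_valid
    neg_adc_clip = v.modality == "ADC"
    if neg_adc_clip:
        out = np.maximum(out, 0.0)
    return VolumeImage(target, out, v.modality, valid)


def compute_adc(b0: VolumeImage, b1000: VolumeImage, b_value: float = 1000.0) -> VolumeImage:
    """ADC map from a two-point DWI acquisition.

    ADC(x) = (1e6 / b) * ln(S_b0 / S_b), in 1e-6 mm^2/s.  Voxels where
    either signal is non-positive are set to 0 and flagged invalid in the
    result's ``valid_mask``; negative ADC (S_b > S_b0, a noise artefact)
    is clipped to 0.
    """
    if b_value <= 0:
        raise ValueError(f"b-value must be positive, got {b_value}")
    if not b0.grid.same_geometry(b1000.grid):
        raise ValueError("DWI volumes are on different grids")
    s0 = b0.values
    s1 = b1000.values
    valid = (s0 > 0) & (s1 > 0)
    adc = np.zeros_like(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = (1e6 / b_value) * np.log(s0[valid] / s1[valid])
    adc = np.maximum(adc, 0.0)
    if b0.valid_mask is not None:
        valid = valid & b0.valid_mask
    if b1000.valid_mask is not None:
        valid = valid & b1000.valid_mask
    return VolumeImage(b0.grid, adc, "ADC", valid)
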
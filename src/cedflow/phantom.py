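"""Synthetic paired pre/post-infusion brainstem cases with full ground truth.

Each case emulates the imaging situation in intermittent convection-enhanced
delivery (CED) to a pontine tumor: a pre-infusion session showing a tumor of
elevated T2W signal and facilitated diffusion inside normal-appearing white
matter (NAWM), and a post-infusion session in which the infusate has soaked
the tumor and pushed a rim of elevated signal beyond its margin.  The scene
is built from analytic ellipsoids so every downstream stage (segmentation,
registration, subtraction, volumetry) can be checked against exact truth:

* ``tumor_mask_pre`` — the voxelized tumor ellipsoid;
* ``tumor_plus_infusate_mask`` — the infusate-soaked region post infusion
  (tumor plus an added rim);
* the rim is grown voxel-by-voxel, ordered by distance from the infusate
  centre, to *exactly* the voxel count corresponding to the infused volume
  Vi, so the change in lesion volume equals Vi by construction (the 1:1
  infused-volume-to-volume-change relationship the analysis is built to
  recover);
* a known rigid inter-session misalignment;
* an NAWM reference region;
* Rician (magnitude-MRI) noise.

DWI is synthesised as a two-point acquisition (b = 0 and 1000 s/mm^2) so
that the ADC computation recovers the scene's diffusion levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageGrid, VolumeImage, compute_adc
from .transforms import RigidTransform

__all__ = [
    "TissueLevels",
    "PhantomSpec",
    "PhantomCase",
    "add_rician_noise",
    "generate_case",
    "generate_cohort",
    "default_cohort_ranges",
]

TISSUES = ("background", "csf", "nawm", "tumor", "soaked")


@dataclass(frozen=True)
class TissueLevels:
    """Per-tissue signal levels for each synthesised modality.

    T1W/T2W/DWI-b0 levels are in arbitrary scanner units; ``diffusion`` is
    the true diffusivity in 1e-6 mm^2/s (what an ADC map should read).
    ``soaked`` is the level inside the infusate-soaked region post infusion;
    T1W is left unchanged by infusate (it carries no ``soaked`` entry),
    which is why T1W anchors the inter-session registration.

    Defaults put the pre-infusion T2 lesion/NAWM ratio at 2.6 and the
    post-infusion ratio at 6.3, and the lesion diffusivity at 1100 pre /
    1750 post — the dynamic range reported for pontine tumors before and
    after infusion.
    """

    t2w: dict = field(default_factory=lambda: dict(
        background=30.0, csf=800.0, nawm=100.0, tumor=260.0, soaked=630.0))
    t1w: dict = field(default_factory=lambda: dict(
        background=30.0, csf=80.0, nawm=300.0, tumor=200.0))
    dwi_b0: dict = field(default_factory=lambda: dict(
        background=50.0, csf=700.0, nawm=400.0, tumor=500.0, soaked=550.0))
    diffusion: dict = field(default_factory=lambda: dict(
        background=300.0, csf=3000.0, nawm=800.0, tumor=1100.0, soaked=1750.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Full ground-truth description of one synthetic paired-session case."""

    grid: ImageGrid = field(default_factory=lambda: ImageGrid.isotropic((96, 96, 64)))
    brain_semiaxes_mm: tuple = (42.0, 36.0, 27.0)
    csf_thickness_mm: float = 2.5
    # Paired CSF "ventricles", offset anteriorly and laterally: triaxial brain
    # plus these keeps every rigid DOF identifiable for registration.
    ventricle_centers_mm: tuple = ((14.0, 18.0, 10.0), (-14.0, 18.0, 10.0))
    ventricle_semiaxes_mm: tuple = (5.0, 10.0, 6.0)
    tumor_center_mm: tuple = (0.0, 0.0, 0.0)
    tumor_semiaxes_mm: tuple = (20.0, 17.0, 14.0)
    infusate_center_mm: tuple | None = None   # defaults to the tumor centre
    vi_ml: float = 4.4
    levels: TissueLevels = field(default_factory=TissueLevels)
    session_shift: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_sigma: float = 5.0
    pv_blur_sigma_vox: float = 0.425  # FWHM of 1 voxel; 0 disables the partial-volume blur
    b_value: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.vi_ml <= 0:
            raise ValueError("infused volume Vi must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.pv_blur_sigma_vox < 0:
            raise ValueError("partial-volume blur sigma must be non-negative")
        center = self.infusate_center_mm
        if center is None:
            center = self.tumor_center_mm
        object.__setattr__(self, "infusate_center_mm", tuple(float(c) for c in center))
        rel = (np.asarray(self.infusate_center_mm) - np.asarray(self.tumor_center_mm)) \
            / np.asarray(self.tumor_semiaxes_mm)
        if np.sum(rel ** 2) > 1.0:
            raise ValueError("infusate centre lies outside the tumor ellipsoid")

    @property
    def tumor_volume_analytic_ml(self) -> float:
        a, b, c = self.tumor_semiaxes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    @property
    def rim_voxel_count(self) -> int:
        return int(round(self.vi_ml * 1000.0 / self.grid.voxel_volume_mm3))


@dataclass
class PhantomCase:
    """One generated case: images per session plus the truth record."""

    spec: PhantomSpec
    pre_session: dict    # modality -> VolumeImage
    post_session: dict
    truth: dict          # masks on the pre grid + scalars

    @property
    def vi_true_ml(self) -> float:
        return self.truth["vi_true_ml"]


def _ellipsoid(points: np.ndarray, center, semiaxes) -> np.ndarray:
    rel = (points - np.asarray(center, dtype=float)) / np.asarray(semiaxes, dtype=float)
    return np.sum(rel ** 2, axis=-1) <= 1.0


def add_rician_noise(v: VolumeImage, sigma: float, seed=None) -> VolumeImage:
    """Corrupt a magnitude image with Rician noise.

    Each voxel x becomes sqrt((x + n1)^2 + n2^2) with n1, n2 independent
    zero-mean Gaussians of standard deviation ``sigma`` (Gaussian noise in
    the two complex channels before the magnitude operation).  sigma = 0
    returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return v
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=v.values.shape)
    n2 = rng.normal(0.0, sigma, size=v.values.shape)
    noisy = np.sqrt((v.values + n1) ** 2 + n2 ** 2)
    return v.with_values(noisy)


def _grow_rim(spec: PhantomSpec, parenchyma: np.ndarray, tumor: np.ndarray,
              world: np.ndarray) -> np.ndarray:
    """Grow the infusate rim outside the tumor to the exact Vi voxel count.

    Candidate voxels (parenchyma, not tumor) are taken in order of distance
    from the infusate centre, with a deterministic index tie-break.
    """
    k = spec.rim_voxel_count
    candidates = parenchyma & ~tumor
    idx = np.flatnonzero(candidates.ravel())
    if idx.size < k:
        raise ValueError("grid too small: not enough parenchyma to hold the infusate rim")
    d = np.linalg.norm(world.reshape(-1, 3)[idx] - np.asarray(spec.infusate_center_mm), axis=1)
    order = np.lexsort((idx, d))
    rim = np.zeros(tumor.size, dtype=bool)
    rim[idx[order[:k]]] = True
    return rim.reshape(tumor.shape)


def _render_levels(spec: PhantomSpec, levels_by_tissue: dict, points: np.ndarray,
                   rim_mask: np.ndarray, post: bool) -> np.ndarray:
    """Evaluate the piecewise-constant scene at arbitrary world points.

    The rim is a voxel set on the pre grid; membership at off-grid points is
    resolved by nearest-voxel lookup so the identical region can be rendered
    in the rigidly shifted post frame.
    """
    shape = points.shape[:-1]
    pts = points.reshape(-1, 3)
    brain = _ellipsoid(pts, (0.0, 0.0, 0.0), spec.brain_semiaxes_mm)
    inner = _ellipsoid(pts, (0.0, 0.0, 0.0),
                       np.asarray(spec.brain_semiaxes_mm) - spec.csf_thickness_mm)
    ventricles = np.zeros(pts.shape[0], dtype=bool)
    for center in spec.ventricle_centers_mm:
        ventricles |= _ellipsoid(pts, center, spec.ventricle_semiaxes_mm)
    ventricles &= inner
    tumor = (_ellipsoid(pts, spec.tumor_center_mm, spec.tumor_semiaxes_mm)
             & inner & ~ventricles)

    out = np.full(pts.shape[0], levels_by_tissue["background"], dtype=np.float64)
    out[brain & ~inner] = levels_by_tissue["csf"]
    out[inner] = levels_by_tissue["nawm"]
    out[ventricles] = levels_by_tissue["csf"]
    out[tumor] = levels_by_tissue["tumor"]
    if post and "soaked" in levels_by_tissue:
        src_idx = spec.grid.world_to_index(pts)
        in_rim = ndimage.map_coordinates(
            rim_mask.astype(np.float64), src_idx.T, order=0, mode="constant", cval=0.0
        ).astype(bool)
        out[tumor | (in_rim & inner & ~ventricles)] = levels_by_tissue["soaked"]
    return out.reshape(shape)


def _blur(img: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return img
    return ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one paired pre/post case; bit-identical for a fixed seed.

    The pre session is rendered on the spec grid.  The post session is
    rendered analytically at rigidly transformed world coordinates (the
    ``session_shift`` maps post-grid world positions into the scene frame),
    so at ``noise_sigma = 0`` the post images equal the transformed
    noise-free scene exactly, with no interpolation residue.
    """
    grid = spec.grid
    world = grid.world_coordinates()

    pts = world.reshape(-1, 3)
    inner = _ellipsoid(pts, (0.0, 0.0, 0.0),
                       np.asarray(spec.brain_semiaxes_mm) - spec.csf_thickness_mm)
    tumor = (_ellipsoid(pts, spec.tumor_center_mm, spec.tumor_semiaxes_mm) & inner)
    ventricles = np.zeros(pts.shape[0], dtype=bool)
    for center in spec.ventricle_centers_mm:
        ventricles |= _ellipsoid(pts, center, spec.ventricle_semiaxes_mm)
    ventricles &= inner
    inner = inner.reshape(grid.shape)
    tumor = (tumor & ~ventricles).reshape(grid.shape)
    ventricles = ventricles.reshape(grid.shape)
    if not tumor[1:-1, 1:-1, 1:-1].any() or tumor.sum() < 100:
        raise ValueError("grid too small: tumor ellipsoid barely voxelizes")

    rim = _grow_rim(spec, inner & ~ventricles, tumor, world)
    soaked = tumor | rim

    # NAWM reference region: parenchyma well clear of the lesion and of CSF.
    exclusion = _ellipsoid(pts, spec.tumor_center_mm,
                           np.asarray(spec.tumor_semiaxes_mm) + 10.0).reshape(grid.shape)
    core = _ellipsoid(pts, (0.0, 0.0, 0.0),
                      np.asarray(spec.brain_semiaxes_mm) - spec.csf_thickness_mm - 3.0)
    nawm_mask = core.reshape(grid.shape) & ~exclusion & ~soaked & ~ventricles

    lv = spec.levels
    modality_levels = {"T2W": lv.t2w, "T1W": lv.t1w, "DWI_b0": lv.dwi_b0}

    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    def make_session(post: bool, points: np.ndarray, seed_offset: int) -> dict:
        images = {}
        diffusion = _render_levels(spec, lv.diffusion, points, rim, post)
        diffusion = _blur(diffusion, spec.pv_blur_sigma_vox)
        for i, (mod, levels) in enumerate(modality_levels.items()):
            scene = _render_levels(spec, levels, points, rim, post)
            scene = _blur(scene, spec.pv_blur_sigma_vox)
            if mod == "DWI_b0":
                b0 = scene
                b1000 = b0 * np.exp(-spec.b_value * diffusion * 1e-6)
                images["DWI_b0"] = add_rician_noise(
                    VolumeImage(grid, b0, "DWI_b0"), spec.noise_sigma,
                    int(seeds[seed_offset + i]))
                images["DWI_b1000"] = add_rician_noise(
                    VolumeImage(grid, b1000, "DWI_b1000"), spec.noise_sigma,
                    int(seeds[seed_offset + 3]))
            else:
                images[mod] = add_rician_noise(
                    VolumeImage(grid, scene, mod), spec.noise_sigma,
                    int(seeds[seed_offset + i]))
        return images

    pre_session = make_session(False, world, 0)
    post_points = spec.session_shift.apply(world.reshape(-1, 3)).reshape(world.shape)
    post_session = make_session(True, post_points, 4)

    truth = {
        "tumor_mask_pre": tumor,
        "rim_mask": rim,
        "tumor_plus_infusate_mask": soaked,
        "nawm_mask": nawm_mask,
        "vi_true_ml": spec.rim_voxel_count * grid.voxel_volume_mm3 / 1000.0,
        "session_shift": spec.session_shift,
        "seed_point_mm": tuple(float(c) for c in spec.tumor_center_mm),
    }
    return PhantomCase(spec=spec, pre_session=pre_session,
                       post_session=post_session, truth=truth)


def case_adc(case: PhantomCase, session: str) -> VolumeImage:
    """Convenience: scanner-style ADC map for one session of a case."""
    images = case.pre_session if session == "pre" else case.post_session
    return compute_adc(images["DWI_b0"], images["DWI_b1000"], case.spec.b_value)


def default_cohort_ranges() -> dict:
    """Study-condition sampling ranges for a synthetic cohort.

    Vi spans the infused volumes reported for day-1 CED (3.8-5.7 ml);
    tumor size is scaled so pre-infusion lesion volumes span roughly the
    reported 12-28 ml; inter-session misalignment is a few millimetres and
    degrees, as expected for a re-positioned head between sessions.
    """
    return {
        "vi_ml": (3.8, 5.7),
        "tumor_scale": (0.85, 1.10),
        "shift_translation_mm": (-2.5, 2.5),
        "shift_rotation_deg": (-3.0, 3.0),
    }


def generate_cohort(n_cases: int, spec_ranges: dict | None = None, seed: int = 0,
                    base_spec: PhantomSpec | None = None):
    """Draw ``n_cases`` case specs reproducibly from per-field ranges.

    Returns ``(cases, truth_table)`` where the truth table records per-case
    Vi and tumor volumes.  Degenerate ranges (lo == hi) pin the value.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    ranges = dict(default_cohort_ranges())
    if spec_ranges:
        ranges.update(spec_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases, rows = [], []
    for i in range(n_cases):
        u = lambda key: rng.uniform(*ranges[key])
        scale = u("tumor_scale")
        shift = RigidTransform(
            rotation_deg=[u("shift_rotation_deg") for _ in range(3)],
            translation_mm=[u("shift_translation_mm") for _ in range(3)],
        )
        spec = replace(
            base,
            tumor_semiaxes_mm=tuple(scale * s for s in base.tumor_semiaxes_mm),
            vi_ml=u("vi_ml"),
            session_shift=shift,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_case(spec)
        cases.append(case)
        rows.append({
            "case_id": i + 1,
            "vi_true_ml": case.vi_true_ml,
            "tumor_volume_true_ml":
                case.truth["tumor_mask_pre"].sum() * spec.grid.voxel_volume_mm3 / 1000.0,
            "soaked_volume_true_ml":
                case.truth["tumor_plus_infusate_mask"].sum() * spec.grid.voxel_volume_mm3 / 1000.0,
        })
    return cases, pd.DataFrame(rows)
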
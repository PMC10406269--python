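"""End-to-end orchestration: simulate -> segment -> align/subtract -> quantify.

Stages communicate through plain files (NIfTI volumes + JSON/YAML sidecars)
when run from disk, so every stage is independently re-runnable and
auditable; the same logic is importable for in-memory phantom cases.  Every
run emits a manifest recording parameters, the seed, per-stage transforms
and checksums of the numeric outputs, and reruns with the same inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import VolumeImage, compute_adc, read_volume, resample, write_volume
from .phantom import PhantomCase
from .quantification import (CaseMetrics, case_metrics, cohort_summary,
                             nawm_reference, pearson)
from .registration import SubtractionMap, align_post_adc, subtract_adc
from .segmentation import auto_params, mask_stats, segment_lesion
from .transforms import RigidTransform

__all__ = [
    "CaseInputs",
    "CaseResult",
    "run_case",
    "run_cohort",
    "write_case",
    "load_case",
    "registration_error",
]

log = logging.getLogger("cedflow")

MODALITY_FILES = ("T1W", "T2W", "DWI_b0", "DWI_b1000")


@dataclass
class CaseInputs:
    """Everything one case run needs; ``truth`` is present for phantoms."""

    case_id: object
    pre: dict                  # modality -> VolumeImage
    post: dict
    nawm_mask: np.ndarray      # reference ROI on the pre grid
    seed_point_mm: tuple       # analyst's bubble location (pre-session world)
    vi_ml: float               # infused volume from the pump record
    b_value: float = 1000.0
    truth: dict | None = None

    @classmethod
    def from_phantom(cls, case: PhantomCase, case_id=None) -> "CaseInputs":
        return cls(
            case_id=case_id,
            pre=dict(case.pre_session),
            post=dict(case.post_session),
            nawm_mask=case.truth["nawm_mask"],
            seed_point_mm=case.truth["seed_point_mm"],
            vi_ml=case.vi_true_ml,
            b_value=case.spec.b_value,
            truth=case.truth,
        )


@dataclass
class CaseResult:
    metrics: CaseMetrics
    subtraction: SubtractionMap
    transforms: dict           # stage name -> RigidTransform
    manifest: dict
    masks: dict = field(default_factory=dict)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _session_adc(images: dict, b_value: float) -> VolumeImage:
    if "ADC" in images:
        return images["ADC"]
    try:
        return compute_adc(images["DWI_b0"], images["DWI_b1000"], b_value)
    except KeyError as exc:
        raise ValueError(f"missing modality for ADC computation: {exc}") from exc


def run_case(inputs: CaseInputs, levels: int = 3, seg_kwargs: dict | None = None) -> CaseResult:
    """Execute the full quantitative pipeline on one paired case.

    Order of stages: ADC computation, composed rigid alignment (which also
    yields the inter-session transform used to carry the NAWM reference and
    the seed point into the post session), four segmentations (T2W and ADC,
    pre and post), subtraction map, per-case metrics.  A stage failure
    raises with the stage named; nothing computed earlier is mutated.
    """
    seg_kwargs = seg_kwargs or {}
    for mod in MODALITY_FILES[:2]:
        for label, session in (("pre", inputs.pre), ("post", inputs.post)):
            if mod not in session:
                raise ValueError(f"stage alignment: missing {label}-session {mod}")

    adc_pre = _session_adc(inputs.pre, inputs.b_value)
    adc_post = _session_adc(inputs.post, inputs.b_value)
    log.info("case %s: ADC maps computed", inputs.case_id)

    aligned_post_adc, transforms = align_post_adc(
        adc_pre, inputs.pre["T1W"], adc_post, inputs.post["T1W"],
        levels=levels, return_transforms=True)
    inter = transforms["t1_post->t1_pre"]   # maps pre-session world -> post-session world
    log.info("case %s: alignment done, inter-session translation %s mm",
             inputs.case_id, np.round(inter.translation_mm, 3))

    # Carry the reference ROI and the seed bubble into the post session.
    nawm_pre = np.asarray(inputs.nawm_mask, dtype=bool)
    nawm_img = VolumeImage(adc_pre.grid, nawm_pre.astype(float), "T2W")
    nawm_post = resample(nawm_img, inputs.post["T2W"].grid, inter.inverse(),
                         interpolation="nearest").values.astype(bool)
    seed_pre = tuple(np.asarray(inputs.seed_point_mm, dtype=float))
    seed_post = tuple(inter.apply(np.asarray(seed_pre)))

    def segment(image: VolumeImage, nawm: np.ndarray, seed) -> tuple:
        params = auto_params(image, nawm, seed, **seg_kwargs)
        return segment_lesion(image, params), params

    pre_t2, p1 = segment(inputs.pre["T2W"], nawm_pre, seed_pre)
    post_t2, p2 = segment(inputs.post["T2W"], nawm_post, seed_post)
    pre_adc, p3 = segment(adc_pre, nawm_pre, seed_pre)
    post_adc, p4 = segment(adc_post, nawm_post, seed_post)
    log.info("case %s: volumes T2 %.2f/%.2f ml, ADC %.2f/%.2f ml", inputs.case_id,
             pre_t2.volume_ml, post_t2.volume_ml, pre_adc.volume_ml, post_adc.volume_ml)

    nawm_mean_pre = nawm_reference(inputs.pre["T2W"], nawm_pre)
    nawm_mean_post = nawm_reference(inputs.post["T2W"], nawm_post)

    metrics = case_metrics(
        pre_t2, post_t2, pre_adc, post_adc,
        nawm_mean_pre, nawm_mean_post, inputs.vi_ml, case_id=inputs.case_id)

    # Subtraction is read inside brain parenchyma: a DWI-signal floor removes
    # the air background (ADC is noise there) and the ADC segmentation's
    # CSF-level upper threshold removes CSF, whose high diffusivity makes the
    # difference noise-dominated as well.
    parenchyma = adc_pre.values < p3.upper_threshold
    if "DWI_b0" in inputs.pre:
        b0 = inputs.pre["DWI_b0"].values
        parenchyma &= b0 > 0.5 * float(b0[nawm_pre].mean())
    subtraction = subtract_adc(adc_pre, aligned_post_adc, tau=None,
                               nawm_mask=nawm_pre, analysis_mask=parenchyma)
    log.info("case %s: subtraction tau %.1f, Vd %.2f ml",
             inputs.case_id, subtraction.tau, subtraction.vd_ml)

    manifest = {
        "case_id": inputs.case_id,
        "vi_ml": inputs.vi_ml,
        "b_value": inputs.b_value,
        "registration_levels": levels,
        "segmentation_params": {
            "T2W_pre": {"lower": p1.lower_threshold, "upper": p1.upper_threshold},
            "T2W_post": {"lower": p2.lower_threshold, "upper": p2.upper_threshold},
            "ADC_pre": {"lower": p3.lower_threshold, "upper": p3.upper_threshold},
            "ADC_post": {"lower": p4.lower_threshold, "upper": p4.upper_threshold},
        },
        "transforms": {k: t.to_dict() for k, t in transforms.items()},
        "subtraction": {"tau": subtraction.tau, "plateau": subtraction.plateau,
                        "positive_volume_ml": subtraction.positive_volume_ml,
                        "vd_ml": subtraction.vd_ml},
        "metrics": metrics.as_dict(),
        "checksums": {
            "difference": _checksum(subtraction.difference),
            "pre_t2_mask": _checksum(pre_t2.mask),
            "post_t2_mask": _checksum(post_t2.mask),
            "pre_adc_mask": _checksum(pre_adc.mask),
            "post_adc_mask": _checksum(post_adc.mask),
        },
    }
    return CaseResult(
        metrics=metrics, subtraction=subtraction, transforms=transforms,
        manifest=manifest,
        masks={"pre_t2": pre_t2, "post_t2": post_t2,
               "pre_adc": pre_adc, "post_adc": post_adc},
    )


def registration_error(estimated: RigidTransform, truth: RigidTransform) -> dict:
    """Residual of an estimated inter-session transform against truth.

    ``estimated`` maps pre-session world to post-session world (the
    resampling convention); the phantom ``session_shift`` maps post-grid
    world into the scene frame, so its inverse is the comparable truth.
    The residual is estimated composed with the inverse truth: translation
    error in mm and rotation error in degrees.
    """
    truth_inter = truth.inverse()
    residual = estimated.matrix @ np.linalg.inv(truth_inter.matrix)
    t_err = float(np.linalg.norm(residual[:3, 3]))
    cos = (np.trace(residual[:3, :3]) - 1.0) / 2.0
    r_err = float(np.rad2deg(np.arccos(np.clip(cos, -1.0, 1.0))))
    return {"translation_mm": t_err, "rotation_deg": r_err}


def run_cohort(cases: list, levels: int = 3, out_dir=None) -> dict:
    """Run every case, assemble the cohort table and its statistics.

    Returns a dict with the metrics DataFrame (``table``), the cohort
    ``summary``, per-case manifests, and — when the cases carry phantom
    truth — a ``truth_comparison`` with infused-volume recovery and
    registration-residual statistics.
    """
    if len(cases) < 3:
        raise ValueError("cohort statistics need at least 3 cases; run run_case per case instead")
    results = []
    for i, inputs in enumerate(cases):
        if inputs.case_id is None:
            inputs.case_id = i + 1
        results.append(run_case(inputs, levels=levels))

    table = pd.DataFrame([r.metrics.as_dict() for r in results])
    summary = cohort_summary(table)
    out = {
        "table": table,
        "summary": summary,
        "manifests": [r.manifest for r in results],
        "results": results,
    }

    if all(c.truth is not None for c in cases):
        vi_true = np.array([c.truth["vi_true_ml"] for c in cases])
        dv_adc = table["dV_ADC"].to_numpy()
        dv_t2 = table["dV_T2"].to_numpy()
        reg_err = [
            registration_error(r.transforms["t1_post->t1_pre"], c.truth["session_shift"])
            for r, c in zip(results, cases)
        ]
        out["truth_comparison"] = {
            "pearson_dV_ADC_vs_Vi": pearson(dv_adc, vi_true).estimate,
            "pearson_dV_T2_vs_Vi": pearson(dv_t2, vi_true).estimate,
            "mean_rel_err_dV_ADC": float(np.mean(np.abs(dv_adc - vi_true) / vi_true)),
            "mean_rel_err_dV_T2": float(np.mean(np.abs(dv_t2 - vi_true) / vi_true)),
            "median_translation_err_mm": float(np.median([e["translation_mm"] for e in reg_err])),
            "median_rotation_err_deg": float(np.median([e["rotation_deg"] for e in reg_err])),
            "registration_errors": reg_err,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")
        report = {"summary": summary}
        if "truth_comparison" in out:
            report["truth_comparison"] = {
                k: v for k, v in out["truth_comparison"].items() if k != "registration_errors"}
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "manifests.json").write_text(
            json.dumps(out["manifests"], indent=2, sort_keys=True) + "\n")
    return out


# ---------------------------------------------------------------------------
# On-disk case layout


def write_case(case: PhantomCase, case_dir, write_truth: bool = True) -> None:
    """Write a phantom case as NIfTI volumes plus a YAML sidecar."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    for label, session in (("pre", case.pre_session), ("post", case.post_session)):
        for mod, img in session.items():
            write_volume(img, case_dir / f"{label}_{mod}.nii.gz",
                         sidecar={"session": label, "b_value": case.spec.b_value})
    grid = case.spec.grid
    nawm = VolumeImage(grid, case.truth["nawm_mask"].astype(float), "T2W")
    write_volume(nawm, case_dir / "nawm_mask.nii.gz")
    meta = {
        "vi_ml": float(case.vi_true_ml),
        "b_value": float(case.spec.b_value),
        "seed_point_mm": [float(c) for c in case.truth["seed_point_mm"]],
        "seed": int(case.spec.seed),
    }
    if write_truth:
        for name in ("tumor_mask_pre", "tumor_plus_infusate_mask", "rim_mask"):
            img = VolumeImage(grid, case.truth[name].astype(float), "T2W")
            write_volume(img, case_dir / f"truth_{name}.nii.gz")
        meta["session_shift"] = {
            "rotation_deg": case.spec.session_shift.rotation_deg.tolist(),
            "translation_mm": case.spec.session_shift.translation_mm.tolist(),
        }
    (case_dir / "case.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_case(case_dir, case_id=None) -> CaseInputs:
    """Load a case directory written by :func:`write_case` (or hand-built)."""
    case_dir = Path(case_dir)
    meta = yaml.safe_load((case_dir / "case.yaml").read_text())
    sessions = {}
    for label in ("pre", "post"):
        session = {}
        for mod in MODALITY_FILES + ("ADC",):
            path = case_dir / f"{label}_{mod}.nii.gz"
            if path.exists():
                session[mod] = read_volume(path, modality=mod)
        sessions[label] = session
    nawm = read_volume(case_dir / "nawm_mask.nii.gz").values.astype(bool)
    truth = None
    truth_path = case_dir / "truth_tumor_mask_pre.nii.gz"
    if truth_path.exists():
        truth = {
            "tumor_mask_pre": read_volume(truth_path).values.astype(bool),
            "tumor_plus_infusate_mask":
                read_volume(case_dir / "truth_tumor_plus_infusate_mask.nii.gz").values.astype(bool),
            "vi_true_ml": float(meta["vi_ml"]),
        }
        if "session_shift" in meta:
            truth["session_shift"] = RigidTransform(
                meta["session_shift"]["rotation_deg"],
                meta["session_shift"]["translation_mm"])
    return CaseInputs(
        case_id=case_id if case_id is not None else case_dir.name,
        pre=sessions["pre"],
        post=sessions["post"],
        nawm_mask=nawm,
        seed_point_mm=tuple(meta["seed_point_mm"]),
        vi_ml=float(meta["vi_ml"]),
        b_value=float(meta.get("b_value", 1000.0)),
        truth=truth,
    )
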
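"""Per-case infusion metrics and cohort statistics.

For each case the analysis collects, on the pre- and post-infusion studies:
the T2W-lesion to NAWM signal ratio (T2seg/NAWM), the T2W segmentation
volume, the mean ADC of the segmentation, and the ADC segmentation volume.
The change in segmentation volume (dV) is the imaging estimate of the
infusate volume of distribution, and the change in T2W volume expressed as
a percentage of the pre-infusion T2W volume is the tumor coverage.

Cohort-level analysis: per-column means and sample SDs, paired two-sided
t-tests on the four pre/post pairs, and Pearson correlations of the infused
volume Vi against each pre/post difference.  p-values are computed through
the regularized incomplete beta function; SDs use the n-1 convention.

A 12-patient reference cohort table ships with the package
(:func:`load_reference_table`); its internal consistency (dV and coverage
arithmetic) is validated on load against one-decimal rounding slop.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import special

from .imaging import VolumeImage
from .segmentation import LesionMask

__all__ = [
    "CaseMetrics",
    "StatResult",
    "nawm_reference",
    "t2_ratio",
    "coverage_pct",
    "case_metrics",
    "paired_t",
    "pearson",
    "cohort_summary",
    "load_reference_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "case_id", "V_ADC_pre", "mean_ADC_pre", "V_T2_pre", "ratio_pre",
    "V_ADC_post", "mean_ADC_post", "V_T2_post", "ratio_post",
    "dV_ADC", "dV_T2", "Vi",
]

#: the four pre/post pairs tested, as (label, pre column, post column)
PAIRED_COMPARISONS = [
    ("ratio", "ratio_pre", "ratio_post"),
    ("V_T2", "V_T2_pre", "V_T2_post"),
    ("mean_ADC", "mean_ADC_pre", "mean_ADC_post"),
    ("V_ADC", "V_ADC_pre", "V_ADC_post"),
]


@dataclass(frozen=True)
class CaseMetrics:
    """One row of the per-patient table."""

    case_id: object
    V_ADC_pre: float
    mean_ADC_pre: float
    V_T2_pre: float
    ratio_pre: float
    V_ADC_post: float
    mean_ADC_post: float
    V_T2_post: float
    ratio_post: float
    dV_ADC: float
    dV_T2: float
    Vi: float

    def __post_init__(self):
        for name in ("V_ADC_pre", "V_ADC_post", "V_T2_pre", "V_T2_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ratio_pre", "ratio_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def coverage_pct(self) -> float:
        return coverage_pct(self.dV_T2, self.V_T2_pre)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StatResult:
    """Result of one hypothesis test."""

    kind: str        # "paired_t" or "pearson"
    estimate: float  # t statistic or correlation r
    dof: int
    p_value: float   # two-sided


def nawm_reference(t2: VolumeImage, nawm_mask) -> float:
    """Mean T2W signal over the normal-appearing-white-matter reference region."""
    mask = nawm_mask.mask if isinstance(nawm_mask, LesionMask) else np.asarray(nawm_mask, dtype=bool)
    if t2.valid_mask is not None:
        mask = mask & t2.valid_mask
    if not mask.any():
        raise ValueError("empty NAWM reference mask")
    return float(t2.values[mask].mean())


def t2_ratio(seg_mean: float, nawm_mean: float) -> float:
    """Lesion-to-NAWM signal ratio (T2seg/NAWM), the scanner-normalized SI."""
    if nawm_mean <= 0:
        raise ValueError("NAWM mean must be positive")
    return seg_mean / nawm_mean


def coverage_pct(dV_T2: float, V_T2_pre: float) -> float:
    """Tumor coverage: volume change as a percentage of the pre-infusion volume."""
    if V_T2_pre <= 0:
        raise ValueError("pre-infusion T2 volume must be positive")
    return 100.0 * dV_T2 / V_T2_pre


def case_metrics(
    pre_t2_mask: LesionMask,
    post_t2_mask: LesionMask,
    pre_adc_mask: LesionMask,
    post_adc_mask: LesionMask,
    nawm_mean_pre: float,
    nawm_mean_post: float,
    vi_ml: float,
    case_id=None,
) -> CaseMetrics:
    """Assemble one per-patient row from the four segmentations.

    The T2 masks must carry statistics against the T2W images and the ADC
    masks against the ADC maps of the matching session (enforced through
    the masks' reference-modality tag).
    """
    for m, want in ((pre_t2_mask, "T2W"), (post_t2_mask, "T2W"),
                    (pre_adc_mask, "ADC"), (post_adc_mask, "ADC")):
        if m.reference_modality != want:
            raise ValueError(
                f"mask statistics computed on {m.reference_modality}, expected {want}")
    return CaseMetrics(
        case_id=case_id,
        V_ADC_pre=pre_adc_mask.volume_ml,
        mean_ADC_pre=pre_adc_mask.intensity_mean,
        V_T2_pre=pre_t2_mask.volume_ml,
        ratio_pre=t2_ratio(pre_t2_mask.intensity_mean, nawm_mean_pre),
        V_ADC_post=post_adc_mask.volume_ml,
        mean_ADC_post=post_adc_mask.intensity_mean,
        V_T2_post=post_t2_mask.volume_ml,
        ratio_post=t2_ratio(post_t2_mask.intensity_mean, nawm_mean_post),
        dV_ADC=post_adc_mask.volume_ml - pre_adc_mask.volume_ml,
        dV_T2=post_t2_mask.volume_ml - pre_t2_mask.volume_ml,
        Vi=vi_ml,
    )


def _t_sf_two_sided(t: float, dof: int) -> float:
    # Two-sided Student-t tail through the regularized incomplete beta:
    # P(|T| > t) = I_{dof/(dof+t^2)}(dof/2, 1/2).
    return float(special.betainc(dof / 2.0, 0.5, dof / (dof + t * t)))


def paired_t(pre, post) -> StatResult:
    """Two-sided paired t-test on the differences post - pre."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    return StatResult("paired_t", float(t), n - 1, _t_sf_two_sided(t, n - 1))


def pearson(x, y) -> StatResult:
    """Pearson correlation with a two-sided p-value via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = _t_sf_two_sided(t, n - 2)
    return StatResult("pearson", r, n - 2, p)


def cohort_summary(table: pd.DataFrame) -> dict:
    """Cohort statistics from a per-patient metrics table.

    Returns a dict with per-column ``mean``/``sd``, coverage summary,
    the four paired pre/post t-tests and the four Vi correlations.
    Degenerate comparisons (zero variance) are flagged, not fatal.
    """
    missing = [c for c in TABLE_COLUMNS[1:] if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table is missing columns: {missing}")
    n = len(table)
    if n < 3:
        raise ValueError("cohort statistics need at least 3 cases")

    numeric = [c for c in TABLE_COLUMNS[1:]]
    out: dict = {
        "n": n,
        "mean": {c: float(table[c].mean()) for c in numeric},
        "sd": {c: float(table[c].std(ddof=1)) for c in numeric},
    }
    coverage = 100.0 * table["dV_T2"] / table["V_T2_pre"]
    out["coverage_pct"] = {
        "mean": float(coverage.mean()),
        "sd": float(coverage.std(ddof=1)),
        "min": float(coverage.min()),
        "max": float(coverage.max()),
    }

    out["paired_tests"] = {}
    for label, pre_col, post_col in PAIRED_COMPARISONS:
        try:
            res = paired_t(table[pre_col].to_numpy(), table[post_col].to_numpy())
            out["paired_tests"][label] = {
                "t": res.estimate, "dof": res.dof, "p": res.p_value}
        except ValueError as exc:
            out["paired_tests"][label] = {"error": str(exc)}

    out["vi_correlations"] = {}
    vi = table["Vi"].to_numpy()
    for label, pre_col, post_col in PAIRED_COMPARISONS:
        diff = table[post_col].to_numpy() - table[pre_col].to_numpy()
        key = f"d_{label}"
        try:
            res = pearson(diff, vi)
            out["vi_correlations"][key] = {
                "r": res.estimate, "dof": res.dof, "p": res.p_value}
        except ValueError as exc:
            out["vi_correlations"][key] = {"error": str(exc)}
    return out


def load_reference_table(validate: bool = True) -> pd.DataFrame:
    """The packaged 12-patient reference cohort table.

    ``validate`` checks the internal arithmetic: dV columns must equal the
    post-minus-pre volumes within 0.15 ml (one-decimal rounding of the
    unrounded source data can shift a printed difference by 0.1).
    """
    with resources.files("cedflow.data").joinpath("table3.csv").open("r") as fh:
        df = pd.read_csv(fh)
    if list(df.columns) != TABLE_COLUMNS:
        raise ValueError("reference table has unexpected columns")
    if validate:
        err_adc = (df["V_ADC_post"] - df["V_ADC_pre"] - df["dV_ADC"]).abs().max()
        err_t2 = (df["V_T2_post"] - df["V_T2_pre"] - df["dV_T2"]).abs().max()
        if err_adc > 0.15 or err_t2 > 0.15:
            raise ValueError("reference table dV columns are inconsistent")
    return df
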
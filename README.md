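# cedflow

Quantifying convection-enhanced-delivery (CED) infusate distribution in
brainstem tumors from paired pre/post-infusion MRI.

CED infuses a drug directly into tissue through implanted catheters,
bypassing the blood–brain barrier. The infusate raises the water content of
the tissue it reaches, which shows up on MRI as increased T2W signal and an
elevated apparent diffusion coefficient (ADC). `cedflow` turns a pair of
MRI sessions — one before, one after an infusion — into an estimate of the
infusate's volume of distribution (Vd): the post-infusion ADC map is
rigidly aligned to the pre-infusion study, the lesion is segmented on both
sessions with a seeded, threshold-gated region evolution, and the change in
segmentation volume (dV) is compared against the infused volume (Vi)
recorded by the pump. A subtraction map (post-minus-pre ADC above a noise
floor) gives an independent view of where the infusate went.

Because real infusions come without ground truth, the package also ships a
first-class synthetic-data generator: analytic ellipsoid "brains" with a
tumor, an infusate-soaked region grown to *exactly* Vi, a known
inter-session rigid shift, partial-volume blur and Rician noise — so every
stage (ADC computation, registration, segmentation, volumetry, statistics)
is testable against exact truth.

## Worked example

Generate a case and quantify it (abridged from `examples/02_segment_lesion.py`):

```python
from cedflow import PhantomSpec, generate_case, auto_params, segment_lesion
from cedflow.phantom import case_adc

case = generate_case(PhantomSpec(seed=42))     # Vi = 4.4 ml, default noise
nawm = case.truth["nawm_mask"]                 # reference white matter
seed_point = case.truth["seed_point_mm"]       # analyst's seed bubble

for label, image in [("T2W pre ", case.pre_session["T2W"]),
                     ("T2W post", case.post_session["T2W"]),
                     ("ADC pre ", case_adc(case, "pre")),
                     ("ADC post", case_adc(case, "post"))]:
    params = auto_params(image, nawm, seed_point)   # midpoint threshold rule
    mask = segment_lesion(image, params)
    print(f"{label}: volume {mask.volume_ml:6.2f} ml  "
          f"mean {mask.intensity_mean:7.1f} +/- {mask.intensity_sd:5.1f}")
```

Output:

```
T2W pre : volume  19.96 ml  mean   257.8 +/-   7.9
T2W post: volume  24.34 ml  mean   623.1 +/-  19.6
ADC pre : volume  19.98 ml  mean  1096.0 +/-  33.9
ADC post: volume  24.34 ml  mean  1738.1 +/-  62.9
truth: tumor 19.94 ml, soaked 24.34 ml (difference = Vi = 4.40 ml)
```

The T2W volume change (24.34 − 19.96 = 4.38 ml) recovers the infused
4.40 ml to within one voxel; the mean lesion ADC rises from ≈ 1100 to
≈ 1750, the soaked-tissue level.

Cohort statistics on the packaged 12-patient reference table
(`examples/04_cohort_statistics.py`):

```
mean volumes: ADC 19.8 -> 24.4 ml, T2W 19.4 -> 23.4 ml
mean seg ADC: 1089.0 -> 1732.8
mean T2seg/NAWM ratio: 2.62 -> 6.27
coverage: mean 22.5%, max 36.0%

paired pre/post t-tests:
  ratio      t =  20.31  p = 4.53e-10
  V_T2       t =  11.79  p = 1.39e-07
  mean_ADC   t =  25.40  p = 4.06e-11
  V_ADC      t =  21.47  p = 2.50e-10

correlations of change vs infused volume Vi:
  d_V_T2     r =  0.693  p = 0.0124
  d_V_ADC    r =  0.677  p = 0.0156
```

## What's in the package

| Module | Purpose |
| --- | --- |
| `cedflow.imaging` | grids, NIfTI I/O, resampling, ADC from two-point DWI |
| `cedflow.transforms` | rigid transforms, composition, Euler parameterization |
| `cedflow.phantom` | synthetic paired-session cases with exact ground truth |
| `cedflow.segmentation` | speed image, seeded region growth, automatic thresholds |
| `cedflow.registration` | rigid registration, composed ADC alignment, subtraction maps |
| `cedflow.quantification` | per-case metrics, paired t-tests, Pearson correlations |
| `cedflow.pipeline` | end-to-end case/cohort runs, manifests, on-disk layout |

The `examples/` directory walks through each capability in order;
`docs/methods.md` records the models, parameter choices and limitations,
including what the synthetic data does and does not emulate.

## Command line

```bash
cedflow simulate --n 12 --seed 7 --out cohort/        # phantom cohort + truth
cedflow run-case --case-dir cohort/case_001 --out out/
cedflow run-cohort --cohort-dir cohort --out report/  # metrics.csv, report.json
cedflow segment --image t2w.nii.gz --seeds seeds.yaml --params params.yaml --out mask.nii.gz
cedflow align-subtract --pre-dir pre/ --post-dir post/ --out diff.nii.gz
cedflow cohort-stats --table metrics.csv
```

Every pipeline run writes a manifest with the parameters, estimated
transforms and SHA-256 checksums of the numeric outputs; reruns with the
same seed and configuration are byte-identical.

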
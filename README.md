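# wmpipeline

Synthetic-phantom pipeline for analysing white matter hyperintensities (WMH)
against normal-appearing white matter (NAWM) on multimodal brain MRI:

- **`wmpipeline.phantom`** — generates ground-truth 3-D tissue labels
  (ventricular CSF, white matter, periventricular + deep lesions), structural
  contrasts (T1W/T2W/FLAIR/T2\*W), parametric biomarker maps (FA, MD, MTR, T1)
  with an optional distance-decaying lesion "penumbra", and cohort-level paired
  biomarker draws calibrated to published population tables.
- **`wmpipeline.io`** — NIfTI-1 and CSV I/O with strict grid-compatibility
  checks (no resampling or registration; mismatched grids are rejected).
- **`wmpipeline.segmentation`** — semiautomatic tissue segmentation: channel
  normalisation, red-green colour fusion, greedy minimum-variance colour
  quantization, centroid-rule tissue selection, CSF-dilation mask refinement
  and stroke exclusion.
- **`wmpipeline.shells`** — disjoint NAWM distance shells at nominal 2 mm
  increments around the lesion mask (anisotropy-aware Euclidean distance
  transform), plus fixed-location spherical control ROIs.
- **`wmpipeline.stats`** — paired t tests, pooled-SD Cohen d, empirical ROC
  with Youden-optimal threshold and DeLong CIs, univariate logistic (IRLS),
  severity-trend ANCOVA (Type II SS), nested-model F tests, Pearson chi-square
  incidence tests, and robust (median/MAD) outlier flagging.
- **`wmpipeline.pipeline` / `wmpipeline.cli`** — end-to-end orchestration with
  a YAML config, a fast summary-level study (n = 676) and a small volumetric
  phantom study.

## CLI

```sh
# full run: summary study plus a small volumetric phantom study
wmpipeline run --seed 1 --out-dir results

# summary statistics only (fast)
wmpipeline run --summary-only --seed 1 --out-dir results

# demo subject (~64^3 voxels, NIfTI volumes + ground-truth labels)
wmpipeline fixtures --out-dir fixtures --seed 0

# individual stages
wmpipeline segment --t1w T1W.nii --t2w T2W.nii --t2star T2SW.nii \
    --flair FLAIR.nii --out-dir masks --levels 16
wmpipeline shells --wmh masks/wmh.nii --nawm masks/nawm.nii \
    --maps MD.nii --out shells.csv
wmpipeline stats --summaries summaries.csv --out-dir results
```

`wmpipeline run --config config.yaml` accepts a YAML file with any subset of
the `PipelineConfig` fields (cohort group sizes, biomarker tables, risk-factor
incidence, penumbra amplitude/decay, quantizer levels, shell step/max, grid
shape, noise scale, seed); defaults reproduce the published calibration.

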
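# dcehabitat

Intratumoral habitat radiomics for dynamic contrast-enhanced (DCE) breast
MRI, built as a tested, reusable pipeline:

1. **Phantom simulation** (`dcehabitat.phantom`) — synthetic single-slice
   DCE series (1 pre-contrast + 8 post-contrast phases) with a known lesion
   mask, known per-pixel time-to-peak (TTP) habitat structure and a
   configurable class effect, so every downstream stage is testable without
   patient data.
2. **Segmentation** (`dcehabitat.segmentation`) — subtraction images,
   spatial fuzzy C-means clustering inside a rectangular ROI, morphological
   refinement (largest component, hole filling, 3×3 opening), plus a bypass
   mode for externally supplied masks.
3. **Kinetics** (`dcehabitat.kinetics`) — percent relative enhancement
   against the pre-contrast baseline, earliest-argmax TTP maps, and the
   rapid (TTP 1–4) / medium (5–6) / slow (7–8) habitat partition.
4. **Texture** (`dcehabitat.texture`) — a fixed 488-entry feature bank per
   masked region: 4 histogram moments, 380 GLCM statistics (19 stats ×
   16 directed offsets + 4 per-distance angular means), 44 run-length
   statistics (11 × 4 angles) and 60 wavelet subband scalars (haar /
   deubechies2 / symlet4 × 4 levels × 5 scalars). The 2-D DWT is
   implemented in-package (`_dwt.py`).
5. **Selection** (`dcehabitat.selection`) — variance (< 0.01) and Pearson
   correlation (> 0.95) pre-filters plus three fold-wise selectors: PCA
   (cumulative contribution > 95%), L1-penalized logistic regression with
   inner 5-fold CV, and bidirectional stepwise logistic selection
   (p-enter 0.05 / p-remove 0.1).
6. **Modeling** (`dcehabitat.modeling`) — univariate logistic AUC
   screening, linear SVM with Platt-style calibration, leave-one-out
   cross-validation with *fold-wise* filtering + selection (leakage-free by
   construction), and selection-count feature importance.
7. **Evaluation** (`dcehabitat.evaluation`) — DeLong AUC confidence
   intervals and paired AUC z-test, Youden-point ROC metrics,
   Yates-corrected chi-square and exact Fisher tests (r×2 enumeration),
   and ICC(2,1) interobserver agreement.
8. **I/O + CLI** (`dcehabitat.io_cli`) — NIfTI/TIFF case I/O, PNG masks and
   habitat overlays, YAML run configs, CSV feature tables and manifests,
   and the stagewise pipeline driver.

## Command-line usage

Each stage reads from and writes into a run directory:

```bash
dcehabitat run-all --seed 7 --run-dir runs/demo           # everything
# or stage by stage:
dcehabitat simulate --config cfg.yaml --run-dir runs/demo
dcehabitat segment --run-dir runs/demo
dcehabitat regionalize --run-dir runs/demo
dcehabitat extract --run-dir runs/demo
dcehabitat select-train --run-dir runs/demo
dcehabitat evaluate --run-dir runs/demo
dcehabitat report --run-dir runs/demo
```

Artifacts: `manifest.csv`, per-case phase images, segmentation masks and
habitat label/overlay PNGs, `features.csv` (one row per case × region ×
phase, 488 feature columns), per-combination LOOCV scores and selection
counts under `cv/`, `metrics.json`, and a region × phase AUC grid in
`report.csv` / `report.md`. A rerun with the same config and seed is
bit-identical.

## Python API sketch

```python
from dcehabitat import phantom, segmentation, kinetics, texture, modeling

cfg = phantom.strong_effect_config(n_cases=20, image_size=64, seed=7)
series, truth = phantom.generate_case(cfg, class_label=1, case_seed=1)

sub = segmentation.subtract_phases(series.pre_contrast, series.post_contrast[3])
roi = segmentation.ROIBox.around_mask(truth.lesion_mask, margin=4)
mask = segmentation.segment_lesion(sub, roi)

enh = kinetics.relative_enhancement(series)
labels = kinetics.partition_subregions(kinetics.ttp_map(enh), mask)
features = texture.extract_all(sub, labels.labels == kinetics.RAPID)
```
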
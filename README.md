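# dixonmuscle

Automated 3-D segmentation of individual proximal-leg muscles in Dixon MRI
and volumetric per-muscle fat-fraction (FF%) quantification — the imaging
endpoint used to track fat replacement in muscular dystrophies — exercised
end to end on a synthetic two-leg Dixon phantom with exactly known ground
truth.

**Who it is for.** Researchers in quantitative muscle MRI who want a fully
inspectable, CPU-only reference implementation of the patch-based U-Net
segmentation + FF quantification pipeline: every stage (phantom simulation,
preprocessing, training, inference, postprocessing, quantification,
evaluation) is a small, tested Python module.

## The method

A Dixon acquisition reconstructs water-only (W), fat-only (F), in-phase
(W+F) and out-of-phase (|W−F|) volumes. The proton-density fat fraction is

```
FF% = 100 · F / (F + W)        (per voxel, where F + W > 0)
```

and the clinical endpoint is its mean over each muscle's 3-D segmentation,
plus the muscle volume. Segmentation uses a 3-D U-Net (3×3×3 kernels
everywhere, including strided down-sampling and pre-upsampling
convolutions; 4 convolutional layers in the deepest level; instance
normalisation; additive skips) on 2-channel (OP, IP) single-leg images:
volumes are split at the mid-sagittal plane and the left leg is mirrored to
right-leg orientation. Training samples two random axial slabs per image
per epoch (batch size 1, Adam, voxel-wise cross-entropy, learning rate
halved after 25 epochs without validation improvement); whole volumes are
predicted by coverage-averaging overlapping slabs. Predictions are cleaned
by keeping the two largest 26-connected components per muscle (one per
leg) and filling enclosed cavities. Agreement is scored with per-muscle
Dice (DSC), average symmetric surface distance (ASSD), per-image
generalized DSC, Wilcoxon signed-rank tests and Bland-Altman analysis.

Because the clinical scans are private, the package ships a phantom module
that generates mirror-symmetric two-leg Dixon volumes — subcutaneous fat
rind, femur with fatty marrow, wedge-shaped muscle compartments with
per-muscle infiltration `f` so that `water = (1−f)·S`, `fat = f·S` — with
per-subject anatomical jitter, optional Gaussian channel noise, and
acquisition as 1–3 overlapping axial stacks. Designed FF% is `100·f`
exactly. See `docs/methods.md` for the full model and its limits.

## Worked example

```python
import numpy as np
from dixonmuscle import PhantomConfig, generate_phantom, quantify_scan

config = PhantomConfig(noise_sigma=0.02, seed=7)   # 96x96x48, 6 muscles/leg
dixon, truth = generate_phantom(config)
report = quantify_scan(dixon, truth.labels)
print(report.per_muscle.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"overall FF%: {report.overall_ff_pct:.2f}")
```

prints

```
 muscle_id abbreviation  ff_pct  volume_ml  n_voxels  n_invalid
         1           RF    4.96      24.19      8398          0
         2           VL   20.00      23.82      8272          0
         3           VM   39.99      23.32      8096          0
         4           VI   60.01      27.01      9378          0
         5           PC   80.03      26.52      9210          0
         6           AB   95.03      26.01      9030          0
overall FF%: 51.33
```

The six muscles were designed with infiltration {0.05, 0.20, 0.40, 0.60,
0.80, 0.95}; at 2% channel noise the quantified FF% recovers each designed
value to within a few hundredths of a point, and `volume_ml` is the voxel
count times the 1.2×1.2×2 mm voxel volume. With `noise_sigma=0` the
recovery is exact.

Training and evaluating the miniature study end to end:

```python
from dixonmuscle.protocols import run_mini_study
result = run_mini_study(seed=1)     # ~4 minutes on one CPU
print(result.mean_gdsc_pct)         # held-out generalized DSC, percent
```

## Command line

```bash
dixonmuscle simulate --subjects 8 --muscles 6 --grid 96,96,48 \
    --infiltration 0.0,0.2 --seed 1 --out run/data
dixonmuscle pipeline --config config.yaml      # simulate→train→predict→evaluate
dixonmuscle quantify --water s00_W.nii.gz --fat s00_F.nii.gz \
    --labels s00_labels.nii.gz --out ff_report.csv
dixonmuscle evaluate --pred pred.nii.gz --ref gt.nii.gz --out metrics.csv
```

`pipeline` writes stage artifacts plus a `manifest.json` (config hash,
seed, versions, significance threshold) under the run directory; re-running
with the same config and seed reproduces byte-identical label maps.

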
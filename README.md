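# spcnet

Per-pixel detection of **aggressive** (Gleason pattern ≥ 4) and **indolent**
(Gleason pattern 3) prostate cancer on bi-parametric MRI (T2w + ADC), for
researchers building or evaluating histopathology-supervised lesion
detection pipelines.

Radiologist outlines systematically underestimate lesion extent and miss
some lesions outright, so models trained on them inherit those blind spots.
This package implements the alternative: soft per-voxel labels fused from a
Gleason-pattern map and a pathologist cancer outline (registered from
whole-mount histopathology in real data), a 2.5D branched multi-scale
convolutional network trained with a class-weighted cross-entropy, and the
pixel-, lesion-, and patient-level evaluation framework that goes with it —
including the sextant-negative lesion ROC, the radiologist comparison, and
a combined model. Because cohorts of this kind are not publicly deposited,
a seeded phantom generator reproduces the statistical structure of the data
(geometry, lognormal lesion volumes, coexisting aggressive/indolent
subregions, imperfect radiologist outlines) so every stage runs and is
testable end to end.

## The model in brief

Per voxel, the label is a probability triple `y = (y1, y2, y3)` over
(normal, indolent, aggressive); pathologist-cancer voxels without grade
information get `(0, 0.5, 0.5)`. The network — two sequence-specific
convolutional branches (T2w, ADC) over three adjacent slices, concatenated
into shared multi-scale blocks, every scale emitting an upsampled side
output fused by a 1×1 projection — is trained with

    L = −(1/N) Σ_n Σ_i  w_i · y_i(n) · ln ŷ_i(n),      w_i = M / Σ_m y_i(m),

the inverse-proportion class weights computed over all M training pixels.
A lesion counts as detected when the 90th percentile of the model
probability inside its outline exceeds a threshold; benign sextants
(≥ 95% normal voxels) scored the same way provide the negatives for the
lesion-level ROC. Lesions are 26-connected components of the 3D-closed
cancer mask, filtered at 250 mm³ (evaluation only), and are clinically
significant when ≥ 1% (or ≥ 5%) of their cancer voxels are aggressive.
See `docs/methods.md` for the full account.

## Worked example

Train and evaluate the full pipeline on a small synthetic cohort (32
training + 10 held-out phantoms, 2-fold cross-validation ensemble, ~3 min
on one CPU):

```python
from spcnet import ModelConfig, PhantomParams, PipelineConfig, TrainConfig
from spcnet.pipeline import run_experiment

cfg = PipelineConfig(
    seed=1, n_train_cases=32, n_test_cases=10,
    phantom=PhantomParams.high_contrast(
        in_plane_spacing_mm=0.8, grid=(16, 96, 96), class_mix=(0.2, 0.2, 0.6)),
    target_in_plane_mm=0.625, crop_px=96,
    model=ModelConfig(n_scales=5, branch_depth=2, base_width=8, input_size_px=96),
    train=TrainConfig(epochs=5, batch_size=2, n_folds=2),
)
res = run_experiment(cfg)
print("pixel AUC, aggressive:", round(res["pixel"].entries["aggressive"]["auc"], 3))
print("pixel AUC, normal:    ", round(res["pixel"].entries["normal"]["auc"], 3))
print("lesion AUC, all cancer:", res["lesion_all"].entries["all"]["auc"])
print("lesion AUC, clin. significant:", res["lesion_cs"].entries["cs_1pct"]["auc"])
```

prints

```
pixel AUC, aggressive: 0.929
pixel AUC, normal:     0.948
lesion AUC, all cancer: 1.0
lesion AUC, clin. significant: 1.0
```

i.e., on held-out phantoms the ensemble ranks aggressive voxels above the
rest with AUC 0.93, and separates every cancer lesion from every benign
sextant (AUC 1.0) using the 90th-percentile detection statistic. The
thresholds behind the sensitivity/specificity entries in the same reports
are frozen beforehand on out-of-fold validation pixels (Youden's J).
Phantom lesions are deliberately high-contrast here; the point is an
end-to-end check of the machinery, not a claim about clinical data.

The same experiment runs from the shell, stage by stage, with resumable
on-disk artifacts (NIfTI volumes, manifest and report CSVs, YAML
configs/thresholds):

```sh
spcnet run-all --config cfg.yaml --out runs/demo --seed 1
```

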
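# Methods

This note documents the models and procedures implemented in `spcnet`, the
assumptions behind them, and the design choices made where the published
description of this family of methods leaves the design open.

## Problem and labels

The package detects prostate cancer per pixel on bi-parametric MRI (a T2w
volume and an ADC map on a common grid) and distinguishes three classes:
normal tissue, indolent cancer (Gleason pattern 3), and aggressive cancer
(Gleason pattern ≥ 4). Ground truth comes from two sources that are fused
per voxel:

* a Gleason-pattern map (in real data: a histopathology grading model's
  output registered from whole-mount slides onto MRI) — pattern 3 ⇒
  indolent (0, 1, 0); patterns 4/5 ⇒ aggressive (0, 0, 1). Grade
  information always overrides the pathologist outline.
* a pathologist cancer outline — voxels marked cancer but carrying no grade
  become (0, 0.5, 0.5) and are flagged *ungraded*. They contribute
  fractional mass to training but are excluded when evaluating the indolent
  and aggressive classes.

Everything else is (1, 0, 0). Cancer labels falling outside the prostate
mask are forced to normal with a warning rather than an error, because
histopathology–MRI registration has a known 2–3 mm error in real data.

## Phantom cohorts

Clinical cohorts of this kind are not publicly deposited, so the package
ships a generator of synthetic cases that reproduces the *statistical
structure* the pipeline depends on, not prostate anatomy:

* geometry: sub-millimetre in-plane spacing, 3–4.5 mm slice spacing, a
  smoothed, randomly perturbed ellipsoidal gland of ≈ 40 × 30 × 38 mm
  (≈ 20–30 cm³);
* lesions: connected random blobs grown from an in-gland seed as sublevel
  sets of (distance + smooth noise), with volumes drawn from a lognormal
  with default (μ, σ) = (7.04, 0.96) — mean ≈ 1 800 mm³, SD ≈ 2 200 mm³ —
  rejected outside [50, 20 000] mm³ or when clipped too much by the gland
  boundary; mixed lesions embed an aggressive core strictly inside an
  indolent lesion (core fraction U(0.2, 0.7));
* appearance: lesions hypointense on ADC and mildly hypointense on T2w,
  aggressive voxels darkest on ADC; Gaussian noise (default SD 5% of the
  in-gland base intensity, 3% in the high-contrast preset) plus a ±3%
  smooth multiplicative bias field;
* annotation imperfections: an optional one-voxel ungraded rim per lesion
  (probability 0.3) exercising the 0.5/0.5 path, and a radiologist outline
  that drops each lesion with probability `radiologist_miss_prob` (default
  0.2) and erodes survivors in-plane to `radiologist_shrink_factor`
  (default 0.7) of their area — the documented tendency of MRI reads to
  underestimate lesion extent and miss some lesions entirely.

Per-class lesion contrast is a free parameter of the generator; no public
per-class contrast statistics exist to calibrate it, so the defaults are a
plausible choice and a deliberately easy `high_contrast` preset is provided
for short training schedules. Consequently, passing tests demonstrate that
the pipeline's machinery is correct and that the network can learn a
separable contrast pattern end to end; they do not demonstrate clinical
performance. The phantoms have no zonal anatomy, no scanner artifacts, and
no DCE dynamics.

All phantom randomness flows from `numpy.random.default_rng([seed, case
index])`, so a cohort is bit-reproducible given its seed.

## Preprocessing

1. In-plane resampling to a common spacing (default 0.29 mm; bilinear for
   intensities, nearest-neighbour for masks). Slice spacing is never
   resampled.
2. Cropping to `crop_px` × `crop_px` (default 224) centred on the rounded
   prostate-mask centroid (ties round toward the smaller index), zero-padded
   at grid edges.
3. Histogram-landmark intensity standardization, per sequence: each
   training volume's in-gland intensities are linearly anchored at the
   (1, 99) clip percentiles onto a common [0, 100] range, percentile
   landmarks (default deciles 10…90) are averaged across training volumes,
   and every volume is then mapped onto the mean landmarks by a monotone
   piecewise-linear transform of its in-gland intensities with end-segment
   slope extrapolation. Landmarks are learned once on the training split,
   serialized, and applied frozen to test cases. Whether the underlying
   method rescales before averaging is ambiguous in the literature; the
   anchored-rescale choice is the package's and is configurable.
4. In-gland z-scoring: the affine transform making in-gland mean 0 and SD 1
   is applied to the whole frame.

T2w–ADC co-registration is assumed done upstream (a validation check
rejects mismatched grids); bias-field correction and deformable
registration are out of scope.

## Network

A 2.5D, two-branch, multi-scale convolutional network in the
holistically-nested (HED) idiom. Each sequence's three adjacent slices
enter a private branch (`branch_depth` scales, default 2) of blocks (two
3×3 convolutions + ReLU, then 2×2 max-pool); branch features are
concatenated and shared blocks continue to `n_scales` (default 5) total
scales. Every scale emits a side output — a 1×1 projection to 3 classes,
bilinearly upsampled (fixed, not learned) to the input size — and a fused
head applies a final 1×1 projection to the concatenation of all side
outputs. Softmax is applied at every output; prediction uses the fused
head, and cross-validation ensembles average the fused softmax maps
arithmetically.

Since the published figure of this architecture family does not specify
layer widths numerically, channel width is `min(base_width · 2^scale,
width_cap)` (defaults 16 and 128) and all such knobs are config-exposed.
The context slices enter as channels of a 2D convolution (not 3D
convolution); deep supervision (equal-weight loss on each side output plus
the fused head) defaults on.

The layers are implemented directly on numpy arrays in float64, with
explicit backward passes (im2col convolutions, pooling argmax scatter,
transpose of the fixed interpolation operator). This keeps training and
inference bit-reproducible under a fixed seed on CPU; gradient correctness
is checked against central finite differences in the test suite.

## Training

* Loss: weighted categorical cross-entropy
  `L = −(1/N) Σ_n Σ_i w_i y_i(n) ln ŷ_i(n)` with ε-clipping (ε = 1e-7),
  where `w_i = M / Σ_m y_i(m)` over the entire training set and soft labels
  count fractionally. With these weights each class's total weighted mass
  equals `M`, equalizing expected per-class contributions.
* Scope: the loss sums over in-gland pixels of the selected slices by
  default (`loss_mask="prostate_only"`), consistent with the gland-restricted
  normalization and evaluation; `full_frame` is available.
* Slice selection: cancer-bearing cases contribute only slices containing
  cancer; normal cases contribute all gland-intersecting slices.
* Augmentation: a shared random rotation U(−15°, 15°) and left–right flip
  (p = 0.5) per sample; bilinear for images, nearest-neighbour for labels
  and masks, out-of-frame filled with background/normal.
* Optimization: Adam (β = 0.9/0.999), learning rate 1e-3, default 25
  epochs × batch 32, patient-level k-fold cross-validation (default 5
  folds; folds never split a patient). A NaN loss aborts with a diagnostic.
* Ungraded 0.5/0.5 pixels contribute to both the loss and the class-weight
  counts.

## Lesion machinery

Cancer label masks are 3D-closed with an ellipsoidal structuring element
(default physical radii 3 mm in-plane, 1 mm through-plane — the element size
is not specified in the method family, so it is config-exposed and pinned in
tests); the input is padded first so closing never clips at borders and the
result always contains the input. Lesions are 26-connected components;
components under 250 mm³ are discarded *for evaluation only* (never for
training labels — enforced structurally: the training path never calls the
filter). A lesion's aggressive fraction counts aggressive-argmax voxels
(ungraded excluded) over all cancer voxels including ungraded; clinical
significance is ≥ 1% or ≥ 5% aggressive fraction.

Sextants split the gland at the left–right bounding-box midline (ties to
the left, which takes the extra column for odd spans) crossed with three
contiguous slice tertiles (largest-remainder sizes, e.g. 10 slices →
4/3/3). Whether the published division uses the patient midline or the
gland bounding box is not stated; the bounding box is the package's choice.

## Evaluation

* Pixel level: one-vs-all trapezoidal ROC AUC over pooled in-gland pixels
  of the evaluated slices (cancer-annotated slices for cancer cases, all
  gland slices for normal cases); ungraded pixels excluded for the cancer
  classes. Sensitivity/specificity at frozen thresholds.
* Lesion level: a lesion is detected when the 90th percentile
  (linear-interpolation convention — pinned, because detection can flip on
  small lesions) of the score inside its outline strictly exceeds the
  threshold (a ≥ switch exists). Negatives are ≥ 95%-benign sextants scored
  with the same statistic over the whole gland (restricting negatives to
  evaluated slices is the unstated alternative; whole-gland is the
  package's choice). All-cancer mode scores ŷ₂+ŷ₃ against all lesions;
  clinically-significant mode scores ŷ₃ against CS lesions.
* Patient level: TP if any CS lesion is detected; normal patients are FP
  when thresholding + morphology of the aggressive channel yields any
  predicted lesion. Only Se/Sp are reported (the decision is hard, not a
  score).
* Radiologist comparison: outlines become predictions with ŷ₃ = 1 inside;
  the combined model adds the two channel volumes (scores in [0, 2], not
  probabilities, and flagged as such) and reuses the same percentile rule
  and threshold on the sum — chosen over a logical OR of detections as the
  reading closest to "adding" the predictions.
* Operating thresholds maximize Youden's J on pooled out-of-fold validation
  pixels and are frozen before any test-set evaluation.

AUCs are computed with scikit-learn and cross-checked in the tests against
an independent pairwise Mann–Whitney oracle to 1e-9; sensitivity and
specificity are recomputed from stored confusion counts on every report.

## Scaled-down end-to-end study

The acceptance script and the heaviest test train the full pipeline at
desk scale on one CPU: phantoms at 0.8 mm native / 0.625 mm resampled
in-plane spacing on a (16, 96, 96) grid (a 40 mm gland fits a 96 px crop at
0.625 mm), the high-contrast preset, 32 training + 10 held-out cases
(mix 20% normal / 20% indolent-only / 60% mixed), a narrow network
(base_width 8, 5 scales, 96 px), and 2-fold cross-validation for 5 epochs.
Because this cohort is two orders of magnitude smaller than a clinical
training set, the batch size is scaled down with it: the reference schedule
(~1 000 training slices, batch 32, 25 epochs) performs on the order of 800
optimizer updates, so the scaled run (~180 slices per fold, 5 epochs) uses
batch 2 to keep the update count in the hundreds (~450 per fold) rather
than the tens. All other optimizer settings keep their defaults.

## Numerical choices and degenerate inputs

* float64 throughout the network; bit-identical reruns under a fixed seed.
* Percentiles: numpy linear interpolation everywhere (landmarks, detection
  statistic).
* Centroid ties round toward smaller indices; sextant midline ties go left.
* Degenerate inputs fail loudly: empty prostate masks, constant in-gland
  histograms, zero in-gland SD, a class with zero mass in the training
  pool, glands spanning < 3 slices (sextants) or < 5 slices (phantom), and
  fewer cases than folds all raise validation errors.
* Closing with zero radii, empty cancer masks, and zero-lesion phantoms are
  valid inputs with well-defined outputs.

## Known limitations

The phantoms' simplicity means headline clinical metrics are not
reproduced here; the end-to-end criterion checks learnability and pipeline
correctness, not clinical accuracy. Left–right flip equivariance of the
network is encouraged by augmentation but not guaranteed, and is therefore
not asserted. The numpy backend is CPU-only and sized for small
experiments, not for 224 px × 25-epoch clinical training runs.
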
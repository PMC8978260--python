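# Methods

This note documents the models, the synthetic cohort, and the numerical and
design choices behind `morphseg`. Interfaces are described in the README;
here the focus is on *why* things are the way they are and what the
desk-scale experiments do and do not demonstrate.

## Pipeline overview

The pipeline segments a small (< 0.5% of the volume), elongated organ in
three stages: coarse localization, soft-label prediction inside the
localized region, and refinement by a population morphology prior. All
stages operate on `(row, column, slice)`-ordered voxel grids; bounding boxes
are 0-based with inclusive endpoints.

## Networks and the numpy layer core

Both networks run on a small convolutional core written directly in numpy
with manual backpropagation: im2col-based 3×3×3 convolutions (stride 1
or 2), transposed convolutions with kernel equal to stride (exact,
non-overlapping upsampling), ReLU/sigmoid, the soft Dice loss and Adam.
Forward passes on large grids process the im2col buffer in depth slabs so
memory stays bounded; float32 throughout. Layer gradients are verified
against central finite differences in float64 in the test suite.

Two deliberate architecture choices:

- **One strided convolution per encoder level.** Downsampling and channel
  growth coincide, so the feature-shape walk matches the published grid
  exactly (e.g. 96×96×128×1 → 48×48×64×32 → … → 6×6×8×256 for the
  localizer; 144×208×128×1 → … → 9×13×8×256 for the U-net), and a full-size
  CPU forward pass takes seconds. A conventional two-convs-per-level block
  would add capacity the desk-scale experiments do not need at several
  times the cost.
- **Kernel = stride transposed convolutions.** A stride-4 deconvolution
  with a 3³ kernel would leave uncovered zeros in its output; kernel = 4
  gives exact factor-4 upsampling while preserving the "final upsample of 4
  instead of 2" structure of the localizer decoder.

The U-net decoder fuses each upsampled feature with its skip connection by
a pointwise (1³) convolution; spatial mixing lives in the strided encoder
and the transposed convolutions. The final sigmoid layer's bias is
initialized to −3 in both networks so the initial output probability
(~0.05) is near the foreground prior of a very small organ rather than 0.5
— with the Dice loss and ~0.3% foreground this removes a long initial
plateau.

### Training

Adam, batch size 1, soft Dice loss `1 − 2Σpg/(Σp + Σg + ε)` with
`ε = 10⁻⁷` in the denominator only (so a perfect binary prediction scores
exactly 0 and a fully disjoint one exactly 1). The parameter state with the
best validation loss is kept; with no validation set, the training loss is
used. `TrainConfig` defaults (learning rate 10⁻⁶, up to 1500 epochs) follow
the full-scale protocol of the original study setting; the desk-scale
pipeline preset uses 10⁻³ and 60–120 epochs, which the smoke tests show is
what small inputs and tiny channel widths need.

Dice training at batch size 1 occasionally lands in a dead initialization
(training loss stuck above 0.9 while other seeds train fine). The pipeline
preset therefore retrains from a fresh seeded initialization, up to twice,
whenever the minimum training loss stays above 0.7. The restart is
deterministic given the configuration seed and is recorded in the fold
audit log.

## Phantom cohort

Each phantom is a 3D volume plus a crisp 0/1 reference mask of a curved,
elongated tubular target with a bulky head tapering (≈2.3:1) to a thin
tail. The long axis follows a fixed anatomical base direction with Gaussian
angular jitter (sd 0.3 rad), with randomized bend, scale and position —
like a real organ cohort, subjects share an approximate lie while differing
in shape and position. An isotropic random orientation would make a
population morphology prior structurally meaningless, which is not the
anatomy this generator emulates. Defaults:

| parameter | default | meaning |
|---|---|---|
| `shape` | 64³ (32³ in the desk-scale pipeline preset) | grid size, voxels |
| `target_fraction_range` | (0.001, 0.005) | target volume fraction; a very small organ |
| `n_distractors` | 6 | ellipsoidal blobs with mean intensity within ±10% of the target's |
| `noise_sd` | 0.04 | additive Gaussian intensity noise |
| `smooth_sigma` | 0.8 voxels | Gaussian blur of the *intensity* (never the mask) — fuzzy borders |

The target's voxel count is driven to the sampled fraction by bisection on
a global radius scale; connectivity (single 6-connected component) is
enforced with deterministic retries. Distractors never touch the 1-voxel
dilated target, so ground truth stays unambiguous. One seed drives
everything: phantoms, cohorts, fold splits, weight initialization and epoch
shuffling are bit-reproducible.

What the phantoms do **not** emulate: Hounsfield-calibrated intensities,
organ texture, anisotropic voxel spacing, and the full anatomical context
of an abdomen. Passing tests on phantoms demonstrates that the pipeline's
machinery — localization, cropping, soft labels, prior fusion, threshold
selection, cross-validation bookkeeping — behaves correctly and that the
method's moving parts interact as designed; they say nothing quantitative
about clinical CT performance.

## Localization details

The localizer's training target in the pipeline preset is the reference
mask **dilated by 4 voxels** (`loc_target_dilation`). The stage's job is a
loose boundary around the organ, not its outline; at desk scale, training
the coarse (factor-4 final upsample) decoder against the exact thin-tube
outline memorizes the training cases instead of generalizing, while the
loose-boundary target localizes held-out phantoms with box TPR ≈ 1.0. The
post-processing contract is unchanged: binarize at strictly > 0.5, keep the
largest 6-connected component (ties to the earliest component in scan
order), bounding box with a 2-voxel margin clamped to the grid.

Inside the box the original intensities are kept by default in the desk
preset (`mask_outside=False`); zeroing the voxels outside the candidate
regions (`mask_outside=True`) is available and matches the full-scale
protocol, but with a coarse candidate mask it deletes true-target voxels
and caps the attainable DSC at this scale.

The U-net trains on the trained localizer's own crops of the training
split, plus `unet_crop_jitter = 2` extra crops per case with randomized
box margins (1–7 voxels per side) — robustness to the localizer's box
variability. If a predicted box misses the target entirely (possible early
at desk scale), that *training* case falls back to its reference-label
box; held-out cases never do.

## Morphology prior

`build_prior` implements the multiplicative closed form: a voxel covered by
`k` of `n` aligned labels gets `baseline^(n−k)`, computed in the log domain
(at n = 60 the raw values span ~60 orders of magnitude), then divided by
the maximum so the peak is 1 and nothing is 0. Alignment is
translation-only: centroid pre-alignment followed by an exhaustive ±5-voxel
search maximizing intersection with the running average, plus two groupwise
refinement passes (each label re-fit against the sum of the others).

For *fusion* the pipeline uses the graded **coverage-frequency view** of
the same template: `max(k/n, baseline)`, which is the log-domain magnitude
of the multiplicative map. On an exponential scale the template is
effectively one-hot — only the all-`n` intersection survives any
threshold > 0.5 after fusion — whereas the coverage frequency is the
standard probabilistic-atlas reading ("center bright, periphery darker in
steps") and is what allows the prior to *refine* rather than annihilate
the soft labels. Both modes are exposed (`prior_fusion="coverage"` |
`"product"`).

Two further steps make the atlas usable at n = 15 labels:

- **Smoothing.** The coverage atlas is blurred with a Gaussian of
  `prior_smooth_sigma = 2.5` voxels — the cohort's own positional
  variability scale (position jitter ±2.6 voxels; tail scatter from the
  angular jitter ±2.7) — the usual compensation for finite sample size and
  residual misalignment in atlas construction. The floor value is
  preserved.
- **Per-case alignment.** Before fusion the atlas is integer-shifted onto
  the case's predicted region (centroid match refined by an exhaustive ±5
  search maximizing overlap with the soft map). Desk-scale crop frames are
  target-centered, so without this the atlas would be applied at an
  arbitrary offset. This is the "pre-alignment behind a flag" option, on
  in the pipeline preset; `match_prior` itself stays alignment-free.

Fusion is voxel-wise multiplication followed by min–max rescaling to
[0, 1]; the segmentation threshold is chosen on the training split from the
grid {0.51, …, 0.99} (step 0.01, ties to the smallest), and applied with a
strict `>`. Note the strict inequality also means a false region at
exactly 0.55 is already excluded at τ = 0.55.

## Evaluation and cross-validation

DSC is symmetric and defined as 1 for two empty masks (with a warning) —
empty versus empty is perfect agreement, and 0/0 is otherwise undefined.
Localization TPR/TNR use the whole-grid convention: the prediction is the
box interior, positives are all reference voxels, negatives all others
(an inside-box-only TNR would be identically 0).

Folds are a seeded shuffle dealt round-robin, so sizes differ by at most
one (82 cases → 21/21/20/20). Per fold, the localizer, U-net, prior and
thresholds are derived from the training split only; the audit log records
the split, the prior's label provenance, restarts and best epochs. The
ablation harness reuses the same folds and trained components to evaluate
the six factor combinations (localization × prior × U-net); the
localizer-only row uses the satellite-filtered candidate mask as its
segmentation, and rows without localization train a separate U-net on
whole volumes with the prior built in the whole-volume frame.

## Desk-scale configuration and what it shows

The default `PipelineConfig` runs 20 phantoms at 32³, fourfold CV, tiny
channel widths (localizer 8–64, U-net 16–128), 120/60 epochs — roughly
four minutes on one CPU. Under this preset (seeds 0, 1, 2): localizer box
TPR ≈ 1.0 with ~73–76% of background excluded, and mean held-out DSC with
the prior within 0.01–0.015 of the no-prior pipeline (better in some
folds). The absolute DSC (~0.35–0.45) reflects the tiny training sets and
network widths, not a ceiling of the method.

## Known limitations

- Translation-only alignment; no rotation, scaling or deformable
  registration of labels or atlas.
- The product-form prior is faithful to its closed form but uninformative
  as a fusion factor whenever the all-label intersection is small; the
  coverage view is the operative default.
- Batch size 1 only; no batch/instance normalization.
- Localization failure (no candidate voxel above 0.5) on a held-out case
  raises an error rather than falling back — silent degradation would
  corrupt the evaluation.
- NIfTI probability maps are stored as float32; product-prior values below
  ~1e-38 (n ≳ 40 labels off-coverage) are clamped to the smallest positive
  float32 on disk, preserving the no-zero rule but not the exact value.
  In-memory construction is float64.
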
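# Methods

This note documents the models and procedures `histocurate` implements,
the parameter choices that matter, what the synthetic fixtures do and do
not emulate, and the numerical conventions used throughout.

## Label model and coordinates

Slide pixels carry one byte from the codebook {0 background, 1 stroma,
2 benign epithelium, 3 GS3, 4 GS4, 5 GS5}. Epithelium is defined as
label ≥ 2; the malignant targets are 3–5. Benign is not covered by the
malignant target definition, so benign patch synthesis uses target
label 2 under the same acceptance rule. All coordinates are 0-based and
half-open with x = column, y = row; a window covers
`[x0, x0+w) × [y0, y0+h)`, which makes tiling arithmetic exact (adjacent
zero-overlap windows share no pixel). Masks are stored as paletted PNG:
lossless, diffable, and viewable.

## Window synthesis

Geometry. `window_edge` (default 400) is expressed in full-resolution
slide pixels. Foreground isolation downsamples the slide by
`downsample_factor` (2) and Otsu-thresholds the gray image; tissue is the
darker side. Scanning and scoring run on the mask at that same
downsampled grid, with effective window edge `window_edge / factor`
(200). A 1200 × 1200 slide therefore has a 600 × 600 scan mask and a
5 × 5 grid of windows at overlap 0.5. Patches are cut from the
downsampled image by default; `full_resolution=True` cuts native pixels
instead. The synthesizer accepts a mask at either the slide's resolution
(it downsamples by strided slicing) or already at the scan grid.

Scan grid. Stride is `max(1, round(edge·(1−p_ω)))`; starts anchor at 0,
and a final window flush with the far edge is appended per axis whenever
the strided grid falls short, so the full foreground is covered without
partial windows. The per-axis window count is `ceil((L−edge)/stride)+1`,
monotone in `p_ω` regardless of rounding.

Acceptance. A window passes when epithelial coverage `M/N ≥ p_α = 0.1`
and label purity `≥ p_β = 0.95`, both inclusive (the coverage cut is a
"nominally ≥" rule). The two purity readings:

* `T/N` (target fraction of the whole window) — the literal formula. But
  `T ≤ M` means `T/N ≥ 0.95` implies `M/N ≥ 0.95`, so the coverage test
  can never be the binding constraint; at `p_β = 0.95` it is vacuous.
* `T/M` (target fraction of the labeled epithelium) — "purity of the
  label at the targeted level" among labeled pixels. This keeps both cut
  points meaningful: a window can be 40 % epithelium and still be 100 %
  pure GS3.

`T/M` is the default; `purity_denominator="all"` restores the literal
rule. A window is only a candidate when ≥ 50 % of its pixels are Otsu
foreground (`min_foreground`); the threshold is our choice, since
"windows slide over the identified foreground" fixes no number.

Retention and escalation. `p_ω` runs 0.5, 0.6, 0.7, 0.8 (the step is our
choice; only the endpoints are prescribed). At the first `p_ω` with ≥ 20
accepted windows, the accepted set is sorted by coverage descending with
deterministic `(y0, x0)` tie-breaks and truncated to 20. Slides failing
at `p_ω = 0.8` are excluded. The whole procedure is deterministic: no
seed is taken because none is needed.

Eligibility. Benign ← diagnosis benign; GS3 ← 3+3; GS4 ← 4+4; GS5 ←
4+5/5+4/5+5 (GS5-primary slides are scarce, so secondary-5 slides
contribute). Other diagnoses contribute nothing and are logged.

## Gland extraction

Polygons fill by pixel center: pixel (x, y) belongs to a gland iff
(x+0.5, y+0.5) is strictly inside. An axis-aligned square of side s
fills exactly s² pixels, and glands sharing an integer-coordinate edge
never double-claim a boundary pixel. Overlapping annotations resolve
later-wins with a logged pixel count. Bounding boxes: `tight` is the
minimal integer box; `squared` grows the shorter axis symmetrically (odd
remainder to the low side) so the center is preserved; `fixed` centers a
constant-edge square (the edge is a flag — no canonical value exists) on
the tight center. All boxes clip to the slide with a log entry.

## Preprocessing

Sample-mix with target 300 and rank 3 samples nine 100 × 100 tiles at
independent uniform in-bounds offsets (with replacement — small sources
would otherwise starve) and mosaics them row-major. No interpolation
occurs anywhere, so the mosaic's pixel multiset is a sub-multiset of the
source's and texture scale is untouched. Undersized sources (either
dimension < 100) are removed by default; the `shrink` policy falls back
to the largest divisor of the target that fits and reports the reduced
scale. Mixing is within-image only; tiles are never drawn across glands.

Z-score standardization is per image and per channel with the population
standard deviation (the common image-pipeline convention); constant
channels map to zeros. Dataset-level statistics are a flag away for
ImageNet-style pipelines but are not the default.

## Consensus outlier removal

A committee of `n_models = 20` classifiers — in practice the models of an
MCCV run, here retrained per iteration on 90 % subsamples — each predicts
every training sample. Samples with ≤ 1 correct vote of 20 are removed
(the threshold is exposed; "never or very seldom correct" is
qualitative). Iteration proceeds to a fixed point or 3 rounds. The
consensus table is built over training samples only, so validation data
are structurally untouchable. Removing every sample is an error, not a
silent empty set.

## Training support

Cosine annealing follows the SGDR form
`η(t) = η_min + ½(η_max − η_min)(1 + cos(πt/T))` with `T` = 29 epochs ×
batches per epoch and a warm restart to `η_max` at each boundary; the
exact formula is our choice (only the technique and cycle length are
given). `η_min` defaults to `η_max/100`.

The stage plan encodes coarse-then-fine transfer learning: head-only
then all-groups on the pretraining cohort, repeated on the target cohort
(four stages), or the target pair alone. Execution is verified by
parameter-change tracking against each stage's group mask.

The reference classifier is a small numpy MLP over 9 summary features
(channel means and SDs, gradient energy, lumen fraction, gray-level
spread): features → 16-unit ReLU layer (`feature_extractor` group) →
32-unit aggregation layer → softmax (`classifier_head` group), trained
by minibatch SGD under the cosine schedule. It is the desk-scale test
vehicle; heavyweight CNNs plug in through the same two-group contract
and are intentionally out of scope.

For cross-source training, labels live in the product space source ×
grade (e.g. 2 × 2 = 4 classes); inference reduces scores to grades by
summing over sources, which conserves probability mass and leaves the
grade argmax invariant to how a grade's mass splits across sources.

## Evaluation

MCCV draws each fold's validation set as `round(val_fraction · n)`
subjects uniformly at random (default fraction 0.1, mirroring a 90/10
split), independently across folds; ≥ 20 folds are recommended since
folds are sampled with replacement. Splits are by subject — a slide's
patches never straddle a fold.

Metrics are computed from the contingency table with explicit `None`
for 0/0 ratios; AUC is the Mann–Whitney statistic via average ranks
(ties credit ½), equivalent to trapezoidal ROC area. The headline
numbers pool predictions across folds and compute each metric once
(merge-then-compute, the Forman–Scholz recommendation for F1/AUC under
CV); per-fold vectors are emitted for diagnostics, and the
pooled-vs-averaged F1 divergence is demonstrated in the tests. CIs are
percentile bootstrap at 95 % over subject-level resampling (respecting
within-subject correlation; the resampling unit is our choice);
single-class replicates are skipped and counted.

## Synthetic fixtures

The generator produces what the pipeline needs structurally, not
histological realism:

* a biopsy-core tissue ellipse on light glass, dark enough for Otsu;
* gland blobs whose tight boxes land within 15 % of nominal edges
  {120, 240, 360, 720} px — lumen-ring ellipses for benign/GS3 (lumen
  fractions 0.30/0.12), fused multi-lobed blobs for GS4/GS5;
* masks produced by rasterizing the emitted polygons over a stroma base,
  so mask/polygon consistency holds by construction;
* class-dependent base colors separated far beyond the pixel noise, and
  per-source affine color shifts standing in for staining differences.

Engineered cohort slides are 1200 × 1200 with a single pure-target
region, sized so the default synthesizer accepts 25 windows at
`p_ω = 0.5` and retains 20 without escalation; a 310-slides-per-class run
yields 6,200 patches per class and 24,800 in total. The separable patch
set (used for curation/training/evaluation tests) plants label flips
binomially at a stated rate.

Because textures are stylized and classes are constructed separable,
passing tests demonstrate the *machinery* — counting, filtering,
ranking, splitting, resampling — not clinical discrimination ability.
Real H&E variation (stain chemistry, scanner optics, morphological
ambiguity between adjacent patterns) is far richer than an affine color
shift, and results on fixtures say nothing about accuracy on patient
data.

## Problem sizes and runtime

Default test and acceptance runs use: the full 310-slide-per-class
cohort for the bookkeeping check (~2 minutes), 12 slides per class for
the end-to-end MCCV smoke run, 400 patches per class with a 20-model
committee for the outlier-recovery study, and 100 seeded runs at
n = 100/class with 400 bootstrap replicates for the CI coverage study.
These sizes were chosen so the whole suite completes in a few minutes on
one CPU while keeping every statistical check at the sample sizes its
claim refers to.

## Known limitations

* No pyramidal/DICOM WSI formats, ICC color management, or stain
  normalization (Macenko/Reinhard-style correction is future work).
* No slide-level ISUP composition from patch predictions.
* The reference classifier is not a CNN and its accuracy on real tissue
  is irrelevant by design; it exists to exercise contracts.
* Gland segmentation is an input (annotations), never inferred.
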
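# histocurate

Patch curation, preprocessing, training support and evaluation for
**gland-level Gleason-pattern classification** of prostate biopsy
whole-slide images (WSIs).

Grading prostate adenocarcinoma means recognizing architectural Gleason
patterns (3, 4, 5) in H&E-stained glandular tissue, a task with high
inter-pathologist variability. Classifier pipelines for this problem spend
most of their engineering not in the network but around it: turning labeled
slides into clean, size-normalized, class-balanced patch datasets, pruning
mislabeled training samples, and estimating performance honestly from small
cohorts. `histocurate` packages that machinery as a library plus a
`histocurate` command-line tool, with a synthetic slide generator so every
stage can be exercised end to end without any external data.

## What it implements

**Sliding-window patch synthesis.** A slide's label mask (codebook 0 =
background, 1 = stroma, 2 = benign epithelium, 3/4/5 = Gleason patterns) is
downsampled 2×, Otsu-thresholded to isolate tissue, and scanned with a
400 × 400 window. For each window with `N` pixels, `M` epithelial pixels
(label ≥ 2) and `T` pixels at the target grade, the window is accepted when

```
coverage = M/N ≥ p_α = 0.1    and    purity ≥ p_β = 0.95
```

Purity defaults to `T/M` (target share of the labeled epithelium); the
whole-window reading `T/N` is available via `purity_denominator="all"` but
note that `T/N ≥ 0.95` forces `M/N ≥ 0.95`, which makes the separate
coverage test inert (see `docs/methods.md`). The window overlap `p_ω`
escalates 0.5 → 0.8 in steps of 0.1 until a slide yields at least 20
accepted windows; the top 20 by coverage are retained and slides that
cannot produce 20 are excluded. Slide eligibility follows clinical
diagnosis: benign patches only from benign slides, GS3 from 3+3, GS4 from
4+4, GS5 from 4+5/5+4/5+5.

**Gland extraction.** GeoJSON gland polygons are rasterized with a
pixel-center half-open fill and cut with tight, squared, or fixed bounding
boxes.

**Preprocessing.** *Sample-mix* resizes variably sized gland patches to a
common input size without interpolation: a 3 × 3 mosaic of randomly sampled
100 × 100 tiles yields a 300 × 300 image that preserves texture scale.
Per-image z-score standardization re-centers each color channel to zero
mean, unit variance.

**Curation.** RANSAC-style consensus outlier removal: a committee of ~20
models each predicts every training sample; samples correct ≤ 1 time out of
20 are dropped (validation data are never touched). Bootstrap-balanced
batches draw equal per-class counts with replacement on every update.

**Training support.** SGDR-style cosine-annealed learning rate (29-epoch
cycles with warm restarts), the four-stage coarse/fine transfer-learning
plan, the combined source × grade label space with reduction back to
grades, and a pluggable classifier contract with a lightweight reference
classifier for desk-scale runs.

**Evaluation.** Subject-level Monte Carlo cross-validation (≥ 20 folds),
the seven-metric suite (accuracy, sensitivity, specificity, precision,
NPV, F1, AUC as the Mann–Whitney statistic), merge-then-compute pooling
across folds, and subject-level percentile-bootstrap 95% CIs.

## Worked example

```sh
histocurate fixtures --n-per-class 1 --classes benign,GS3 --seed 0 --out fx
histocurate synthesize --manifest fx/manifest.csv --out syn
```

prints the cohort bookkeeping table

```
         total  benign  GS3  GS4  GS5
slides       2       1    1    0    0
patches     40      20   20    0    0
```

— two eligible slides, each contributing exactly its 20 retained patches
for the class its diagnosis allows. `syn/patches/` holds the patch PNGs
and `syn/patches.csv` their windows, coverage and purity scores. Then

```sh
histocurate samplemix --in syn/patches --seed 1 --out mixed
```

reports `mixed 40 images, removed 0` (all 200 × 200 patches are large
enough for 100 × 100 tiles). On a 12-slide two-class fixture cohort,
`histocurate evaluate` runs 20-fold MCCV with the reference classifier and
prints each metric with its bootstrap CI; the engineered textures are
cleanly separable, e.g. `"auc": {"estimate": 1.0, "ci_low": 1.0,
"ci_high": 1.0}`.

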
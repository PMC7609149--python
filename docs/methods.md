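# Methods

## The model

`threshseg` casts hand-radiograph segmentation as supervised prediction of a
per-image binarization threshold. The underlying assumption is that after
global histogram equalization a hand radiograph is approximately bimodal —
a bright, connected hand/forearm region over a darker background — so a
single well-chosen gray level separates them, and that the right level is
predictable from the image's intensity distribution alone (histogram, mean,
variance). Everything that a global threshold cannot fix — bright markers,
frame fragments, film annotations — is assumed to be *disconnected* from
the hand, so a connectivity filter (region growing from the image center)
completes the mask.

These assumptions bound the method's scope: it cannot separate objects that
touch the hand, cannot recover from images whose foreground/background
modes genuinely overlap after equalization, and presumes the hand overlaps
the image center (a nearest-foreground fallback handles modest off-center
placement).

## Pipeline stages and parameters

**Histogram equalization** uses the discrete CDF mapping
`out = round(255·(cdf(v) − cdf_min)/(N − cdf_min))` with `cdf_min` the count
of the lowest occupied bin. The dialect is pinned because variants (ceiling
vs. round, cdf_min conventions) shift labels by a gray level or two and
would break bit-reproducibility of the label set. Constant images map to
themselves.

**Label search.** Candidates are `⌊mean⌋ − 2k, k = 1…40` (clipped at 1) on
the enhanced image; candidate quality is the Dice coefficient of the
*region-grown* threshold mask against ground truth, because the judgment the
label encodes is about the final cleaned mask, not the raw binarization.
Ties break toward the larger threshold: over-thresholding erodes thin
structure less than under-thresholding floods the background. When the whole
grid scores below an acceptability floor (Dice 0.5), a limited extension
above the mean (10 values, spacing 2, capped at 255) is searched once;
images that still fail are flagged `unlabelable` rather than given a junk
label. The floor is deliberately permissive — its job is only to detect
catastrophic grids, not to grade quality.

**Features** are the 256-bin relative-frequency histogram plus mean and
population variance (258 values). Feature columns are min–max normalized
over the training set and the (min, max) pairs are frozen for test time;
labels stay as raw gray levels so that RMSE keeps physical units. A constant
column maps to 0.5 with a warning.

**Stacked ensemble.** Base learners, in standalone-accuracy rank order:

| learner | key settings |
| --- | --- |
| random forest | 150 trees, max depth 200, sqrt features, OOB scoring |
| extra trees | 100 trees, bootstrap, balanced class weights, seed 30 |
| bagged trees | 100 estimators, 50% feature subsampling, seed 50 |
| AdaBoost | 50 stumps, learning rate 0.1, seed 30 |
| SVC | sigmoid kernel, gamma 0.1, balanced class weights, seed 5 |

These settings are fixed defaults; hyperparameter search is out of scope.
Four learners carry fixed seeds as part of their settings; the random
forest's seed derives from the estimator's `random_state` so one knob
reproduces the whole fit. Each learner is trained under 5-fold
cross-validation and its out-of-fold predictions (predicted threshold
values, one column per learner — not probability vectors, since the label
is ordinal) form the meta-training set for a softmax (multinomial logistic)
regression. Out-of-fold purity is tracked explicitly (`producer_fold`
bookkeeping) and asserted in tests. At inference each learner's five fold
clones predict and are averaged into that learner's meta-feature; averaging
is the canonical choice for ordinal outputs, and `aggregation='refit'`
(single full-data refit per learner) is provided as the alternative since
either deployment convention is defensible. Meta-learner argmax ties break
toward the larger threshold class, mirroring the labeling rule.

**Region growing** keeps the 8-connected component containing the seed
(image center; if background there, the nearest foreground pixel, ties
toward smaller row then column). 8-connectivity is the default because thin
diagonal finger edges at low resolution fragment under 4-connectivity
(available via a flag). The operation never adds pixels, so the cleaned
mask is always a subset of the thresholded one.

**Crop/resize.** The segmented image is the equalized image with background
zeroed, cropped to the mask bounding box padded 5% per side (a fixed
convention chosen for reproducibility), zero-padded to square, and
bilinearly resized to 512 × 512.

**Metrics.** PSNR uses `10·log10(255²/MSE)`; identical images report an
`inf` sentinel which set-level means exclude (with a count) rather than cap.
SSIM is the single global statistic with C1 = (0.01·255)², C2 = (0.03·255)²
— deliberately not the sliding-window mean-SSIM, which is a different
quantity. DSC/JSI define empty-vs-empty as 1.0 (perfect agreement on
absence). A fixed-normalization MSE mode resizes both inputs to 256 × 256 before
averaging; the default normalizes by the true pixel count.

## The phantom generator

Phantoms emulate the intensity structure the pipeline actually consumes: a
bright connected hand-shaped blob (elliptical palm, forearm band, five
finger lobes) covering roughly half a 128 × 128 frame, Gaussian foreground
(mean 180, sd 12) over Gaussian background (mean 70, sd 10), an additive
illumination ramp (amplitude 15) in a random direction, pixel noise (sd 4),
and three small bright distractor blobs placed strictly disjoint from the
hand — so only the connectivity stage, not the threshold, can remove them.
Dataset jitter (foreground mean ±20, background mean ±15, shape scale
0.92–1.08) makes the optimal threshold vary across samples, which is what
turns threshold selection into a non-trivial classification problem. All
randomness flows from one master seed through counter-based per-sample
streams, so datasets are reproducible sample-by-sample.

The hand fraction (~0.44–0.6 across jitter) is chosen so that the
foreground/background boundary of the *equalized* image falls inside the
below-mean candidate grid — the regime a collimated pediatric hand view
occupies. What phantoms do **not** model: bone texture and trabecular
structure, soft-tissue halos, genuine X-ray physics (scatter, beam
hardening), anatomical shape variation, or distractors touching the hand.
Passing the synthetic benchmark therefore demonstrates that the machinery —
label search, stacking, connectivity cleanup, metrics — is correct and
internally consistent, not that clinical-grade accuracy transfers to real
radiographs.

## Benchmark sizes and numerical choices

The default study uses 600 phantoms (500 train / 100 test) at 128 × 128,
the split sizes of the data regime the package targets; the resolution is
the package's own choice, sufficient because every feature the pipeline
uses is a global intensity statistic. Tie tolerance for score and
probability argmax is 1e-12. Degenerate inputs are handled explicitly:
empty masks warn (region growing) or raise (cropping), single-class label
sets refuse to train, unlabelable images are reported, not dropped
silently.

## Known limitations

- The acceptability floor (Dice 0.5) and extension budget (10 steps) are
  conventions; pathological images could in principle need a larger
  extension than allowed.
- The SVC base learner is consistently the weakest on phantom data; it is
  retained because the ensemble's contract is the fixed five-learner set.
- Global SSIM on nearly-binary masks saturates close to 1 and is less
  discriminative than DSC/JSI; it is reported for completeness.
- Serialized models embed fitted scikit-learn estimators and are therefore
  tied to the scikit-learn version that wrote them (a format-version header
  guards the container, not the estimators).
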
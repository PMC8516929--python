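# Methods

`slidemine` implements a weakly-supervised pipeline for slide-level
classification of whole-slide images (WSIs): the motivating task is detecting
gastric diffuse-type adenocarcinoma in endoscopic biopsy WSIs, where the
positive class (poorly-differentiated carcinoma and signet ring cell
carcinoma) is cytologically subtle and labels exist mostly at the slide
level. This note describes the model and training procedure, the synthetic
data used to exercise them, and the numerical and design choices that were
genuinely open.

## Problem setting and model

A WSI is a multi-resolution raster pyramid with physical calibration; we tie
nominal objective power to resolution through mpp(m) = 10/m µm per pixel, so
×20 ≡ 0.5 µm/px and ×10 ≡ 1.0 µm/px. A slide is scored by a tile-level
convolutional classifier applied to fixed-size square tiles extracted from
tissue regions, and the slide probability is the **maximum** tile probability
— the standard max-aggregation reading of multiple-instance learning, which
is appropriate when a single focus of tumour suffices to call the slide
positive.

Tissue is found on a grayscale thumbnail (Rec. 601 luma) by Otsu's
threshold; pixels in the dark class of the split (gray ≤ t, where t is the
between-class-variance argmax with ties broken toward the lowest level) are
tissue. Candidate tiles are enumerated on a sliding-window grid; tiles whose
footprint on the thumbnail mask carries less than `min_tissue_fraction`
(default 0.25) tissue are dropped, as are tiles that would cross the
right/bottom edge (discarded, not padded). Both the Otsu working downsample
and the tissue-fraction criterion are configuration parameters; the
defaults (downsample 32 for clinical-scale slides, 0.25) are our choices.

### Partial fine-tuning

The tile classifier is fine-tuned *partially*: only the affine (scale and
offset) parameters of every batch-normalisation layer plus the final
classification layer are trainable; all convolutional weights stay frozen at
their pretrained values. For EfficientNetB1 with a single-output head this
budget is exactly 63,329 scalars: 2 × 31,024 batch-norm channel parameters
plus 1280 head weights and 1 bias. The package builds EfficientNetB1 as a
structural descriptor (layer kinds and parameter shapes from the compound
scaling recipe, width 1.0 / depth 1.1) sufficient to compute that mask and
count; real pretrained checkpoints remain pluggable.

The head is one sigmoid unit trained with binary cross-entropy. With two
labels the categorical cross-entropy formulation is equivalent up to
parametrisation, and the odd published parameter count (63,329) is only
consistent with a 1-unit head (a 2-unit softmax head would add an even
2 × 1281); we therefore commit to the 1-unit form.

The trainable network shipped for experiments is a deliberately small
stand-in with the same fine-tuning structure: three 3×3-conv → batch-norm →
ReLU → 2×2-average-pool blocks (8, 16, 32 channels), global average
pooling, and the 1-unit head — 145 trainable parameters over frozen random
filters. It is written directly on numpy with manual backpropagation;
gradients are computed only for the fine-tuning mask, and frozen parameters
are bit-identical after any number of optimizer steps (asserted in tests).
Average pooling (rather than max) keeps the backward pass simple and exact.

### Sampling

Positive training slides carry free-hand lesion polygons; tiles are sampled
only from annotated regions. An annotation whose bounding box fits within
one tile yields a single tile centred on the bounding-box centre (clamped
in-bounds near slide edges) — the common case, since most annotations are
smaller than the tile. Larger annotations are covered by an overlapping grid
with stride = tile/2 over the bounding box, keeping tiles that intersect the
polygon; the half-tile stride guarantees every interior point is covered by
at least two tiles without combinatorial blow-up. Unannotated slides
contribute their whole tissue grid.

Balanced batches loop over the label categories in succession over
per-label shuffled slide queues; each drawn slide contributes
`batch_size / num_labels` tiles of its own label (without replacement when
the pool is large enough, with replacement otherwise, so small biopsy
fragments still fill batches). Queues of the scarcer label reshuffle and
recycle (over-sampling). An *epoch* is the point at which every slide has
been drawn at least once — the over-sampling regime leaves "epoch"
underdetermined, and this definition is ours.

### Two-phase training

Phase 1 trains on balanced random batches. Validation loss — tile-level
binary cross-entropy on a fixed, seeded, balanced tile sample drawn once
from the validation slides (tile- vs slide-level tracking is unstated in
the source recipe; tile-level is cheaper and smoother) — is evaluated every
epoch; after 2 consecutive epochs without improvement the loop switches,
exactly once, to hard mining.

Phase 2 alternates inference and training. Per epoch, slides are visited in
a shuffled order; the current model scores **all** tissue tiles of each
slide (annotated positives included — inference is not restricted to
annotations), and the k = 16 tiles scored most wrongly relative to the slide
label (highest-probability tiles on negative slides, lowest on positive)
are appended to a subset. When the subset reaches N = 256 tiles it is
trained on in arrival order in batches of 32 and cleared; a partial subset
persists across epochs. The subset is not re-balanced by label. Training
stops after 10 epochs without validation improvement and the
lowest-validation-loss snapshot is the final model.

The optimizer is Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 0.001
when training from scratch (0.0001 when fine-tuning pretrained weights),
decayed by 0.95 every 2 epochs with the epoch counter shared across both
phases: lr(e) = lr₀ · 0.95^⌊e/2⌋ for 1-based e. Safety caps
(`max_phase1_epochs` = 50, `max_phase2_epochs` = 100) bound the loops when
the validation loss keeps creeping down and the patience rule alone would
not fire; a non-finite loss aborts with diagnostics.

### Inference and two-stage combination

At prediction time the model runs over the tissue-tile grid (default stride
= tile size, i.e. non-overlapping cells, matching the published heatmap
geometry where a 224 px cell at ×20 spans 112 × 112 µm²); the heatmap holds
one probability per tissue cell with non-tissue cells invalid. The slide
probability is the max over valid cells. In the two-stage workflow the
slide-level P(ADC) from an external first-stage model (a pluggable
callable; not re-implemented here) multiplies the second stage's
slide-level probability: P(diffuse-type ADC) = P₂(diffuse | ADC) · P₁(ADC).
Whether the combination is tile-matched or slide-level is unstated in the
source; slide-level is our documented choice, consistent with combining
per-WSI outputs.

### Evaluation

Slide-level ROC AUC (Mann–Whitney), log loss (probabilities clipped to
[1e-15, 1 − 1e-15]), and accuracy/sensitivity/specificity at threshold 0.5
(probability **equal** to the threshold counts as positive). Confidence
intervals are 95% percentile bootstrap over 1000 resamples drawn with
replacement at the slide level (slides are the exchangeable unit);
resamples that lose a label category are redrawn so exactly 1000 values
enter the quantiles. The bootstrap variant (percentile, not BCa) is
recorded in the report metadata.

## Synthetic slides

The generator emulates the gray-level structure of H&E biopsy scans, not
their appearance: near-white background (240 ± 5), darker tissue fragments
(180 ± 15 with a mild eosin-like tint) drawn as smoothly perturbed circles,
and — on positive slides only — lesion regions carrying high-frequency dark
speckle (dots at 60 ± 20, ~2% seed density dilated 3×3) strictly inside a
free-hand-style polygon annotation. Polygons are guaranteed to lie inside a
tissue blob by construction; slides are generated at a single level and the
pyramid is synthesized by repeated 2× area-average downsampling (rounding
half to even) so magnification handling is genuinely exercised. Per-slide
seeds derive from the cohort seed by a fixed affine hash, so cohorts are
stable under reordering and byte-identical across runs.

What this emulates: tissue/background contrast that Otsu separates cleanly;
a lesion texture statistically separable from plain tissue; exact ground
truth (tissue masks, lesion masks, polygons, labels). What it does not:
stain-colour variability, scanner artifacts, pen marks, tissue folds,
nuclear morphology, or any cytological realism. Passing the end-to-end
benchmark therefore demonstrates that the pipeline's machinery — tissue
detection, annotation sampling, balanced streaming, hard mining, partial
fine-tuning, max aggregation, evaluation — is correct and can exploit a
localized texture signal; it says nothing about performance on clinical
slides.

## Benchmark conditions

The end-to-end benchmark generates 768 × 768 px slides at 0.5 µm/px (base
×20, 3-level pyramid), 3 tissue blobs, 2 lesion regions of nominal 140 px
diameter on positives. The pipeline runs at ×10 with 64 px tiles (stride
64), tissue detection at downsample 8, and the toy backbone — a deliberate
scale-down of the clinical geometry (×10/224 on gigapixel slides) that
preserves the ratio of lesion to tile size and every published training
hyperparameter (k = 16, N = 256, batch 32, betas, decay, patience 2/10).
Cohorts are 100 training slides (80 train / 20 validation, half positive)
and 40 held-out; the headline quantity is held-out slide-level ROC AUC.

## Numerical choices and edge cases

- Resampling: area averaging for downscale, bilinear for upscale; integer
  factors use exact block means with round-half-to-even (a 2×2 0/255
  checkerboard averages to 128).
- Coordinate conversions between magnifications multiply by the power ratio
  and round toward zero; a ×20→×10→×20 round trip moves a coordinate < 2 px.
- Otsu ties break to the lowest qualifying level; a single-valued histogram
  is an error (no separable groups), but a blank slide yields an empty mask
  with a warning.
- Hard-tile selection breaks probability ties by row-major tile order; with
  fewer than k tiles, all are returned.
- An annotated slide whose annotations produce no tiles is an error
  (inconsistent ground truth), not an empty pool.
- Bootstrap resamples are drawn from a seeded generator; fixed seeds give
  bit-identical intervals and reports.

## Known limitations

- The numpy backbone is CPU-bound and deliberately small; it is not a
  vehicle for clinical-scale experiments.
- Slide I/O covers pyramidal multi-page TIFF (with calibration metadata in
  the image description) and flat rasters with an explicit mpp override;
  vendor-specific formats are out of scope.
- The first-stage ADC detector of the two-stage workflow is a pluggable
  probability source, not part of this package.
- No data augmentation is applied anywhere (the training recipe does not
  use any).
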
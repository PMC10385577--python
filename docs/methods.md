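# Methods

## The point-mapping model

Point mapping replaces pixel-dense segmentation with tile classification
on an overlapping grid. A photograph of height H and width W is covered
by `n_cols × n_rows` crop regions of fixed size `(crop_w, crop_h)` whose
origins are evenly spaced,

    x0(j) = round(j · (W − crop_w) / (n_cols − 1)),   j = 0 … n_cols − 1,

and analogously in y, so the first tile sits at (0, 0) and the last is
flush with the bottom-right corner (rounding is half-up; a single-column
or single-row grid has stride 0). With the default 16 × 24 grid every
photograph yields 384 tiles, overlapping whenever `n_cols · crop_w > W`.
Each tile is resized to the classifier's 96 × 96 input (bilinear; an
already-96 × 96 tile passes through bitwise unchanged) and classified; a
class-colored dot at the tile center is the segmentation primitive.

The default inference crop size is `(round(W/12), round(H/15))`, the same
cell size as a 12 × 15 whole-tongue training partition, so inference
tiles match the magnification of training patches. Crop size is a
`GridSpec` field and can be overridden per image.

Training data comes from a *non-overlapping* partition: nominal crop
dimensions `round_half_up(W/n_cols) × round_half_up(H/n_rows)`, with the
last row/column clipped (shrunk or extended) to the border so every pixel
is covered exactly once. Half-up rounding matters: an 8 × 12 partition of
a 2592 × 3872 photograph gives 324 × 323 crops, where floor rounding
would give 322-pixel rows. Coordinates are 0-based with half-open pixel
intervals; regions are row-major.

## Classes, masks and labels

Three classes in fixed order: ABNORMAL (0), NORMAL (1), OTHER (2). The
order is the argmax/plurality tie-break everywhere, chosen conservative
toward flagging pathology. Ground truth is a painted annotation image:
pixels within Euclidean RGB distance 60 (default; absorbs JPEG artifacts
of painted annotations) of pure blue are abnormal, of pure green normal,
everything else other. A crop's label is the plurality class of its full
pixel footprint — the same support the classifier sees — not the center
pixel.

Splits are photograph-grouped (all crops of one photograph land in one
split, preventing leakage) and class-stratified by a greedy allocator
that assigns each photograph to the split with the largest remaining
per-class deficit; deterministic given the seed. Realized counts
therefore match the requested fractions only up to photograph-group
granularity. Optional curation filters mirror common practice:
tongue-boundary crops (footprint under 50% tongue pixels) and
class-inconsistent crops (normal-labeled crops from patient photographs,
abnormal-labeled from healthy-subject photographs) can be dropped. Note
that at the 50% threshold the boundary filter is nearly vacuous — a crop
under half tongue is plurality-other already — so callers wanting an
aggressive filter should raise `min_tongue_fraction`.

## Classifier backends

The classifier is a contract (fit / predict / predict_proba on stacks of
96 × 96 × 3 uint8 patches, scikit-learn estimator conventions), with
three backends:

* **SmallCNNClassifier** — 3 conv blocks (3 × 3 kernels, 8/16/32
  channels, ReLU, max-pool 2/4, global average pooling), dropout 0.5,
  softmax head; SGD with learning rate 0.005 and momentum 0.9 on
  categorical cross-entropy; batch size 32, 50 epochs by default, no
  early stopping (batch size and stopping are this package's defaults —
  the standard recipe does not fix them). Written directly in numpy
  (im2col convolutions), which keeps the backend dependency-free and
  makes training bit-reproducible: weight init, epoch shuffling and
  dropout all draw from a single seeded generator in a fixed order.
  Max-pool gradients are routed to *all* tied maxima (deterministic and
  symmetric; ties are measure-zero with float activations). Weights use
  He-normal initialization.
* **TextureBaselineClassifier** — six flip/rotation-invariant statistics
  per patch (mean R, G, B; standard deviation of the Laplacian; fraction
  of pixels exceeding a σ = 3 Gaussian background by 0.06, a bright-blob
  density tuned to papillary dot lattices; fraction of Sobel magnitudes
  above 0.06, an edge density tuned to fissure grooves), standardized,
  then 3 prototypes per class by deterministic k-means. Prediction is a
  softmax over negative squared distances to each class's nearest
  prototype (temperature 0.5). Multiple prototypes, not one centroid,
  because the abnormal class is a union of visually distinct texture
  families; a single centroid falls between them. Fitting is one pass
  ("one effective epoch") and exactly reproducible.
* **OracleClassifier** — answers each crop from the ground-truth mask via
  the plurality rule with one-hot probabilities. It exists for the key
  identity test: a perfect classifier must make the predicted point map
  equal the ground-truth point map point-for-point, hence IoU = 1 and
  AP = 1 end to end.

Deep backbones (VGG16-class networks) are deliberately not part of the
package: their trained weights and the clinical photographs they were
trained on are not available, so layer-level fidelity would be
untestable. The pipeline treats the classifier as pluggable; an external
model can be wrapped in the same contract.

Training-set augmentation is ×4 (identity, horizontal flip, vertical
flip, one 90° rotation), applied to the training split only; all four
are label-preserving for texture classes.

## Evaluation mathematics

**Patch level.** The 3 × 3 confusion matrix (rows = actual) yields
one-vs-rest TP/FP/FN/TN per class and hence precision, recall, F1 and
accuracy = (TP + TN)/total; overall accuracy is trace/total. Zero
denominators report 0 with an explanatory flag. ROC AUC is the
one-vs-rest rank statistic with tie averaging.

**Segmentation level.** Per image and class, G/P/I point counts give
S = G + P − I, TP = I, FP = P − I, FN = G − I, IoU = I/S. (A verbal
definition that sets TP = P − I is internally inconsistent — it makes TP
equal FP — and TP = I is the only assignment compatible with
precision = I/P and recall = I/G.) Counting is over grid points, not
rendered dot pixels: every dot has identical area, so pixel counts are a
constant multiple of point counts and cancel in every ratio. Conventions
for empty sets: with P = 0, precision is 1 if G = 0 (vacuously perfect)
else 0, mirrored for recall; IoU with S = 0 is 1. Macro averages are
unweighted means over images per class; the grand "mean" row is the
unweighted mean of the three class means (this is how the mean-row
convention of the published summary table reproduces: mean of 0.695,
0.590, 0.831 is 0.705).

**Average precision.** One detection per (image, class) with confidence =
mean softmax of the class over the points predicted as the class (0 when
none; averaging over *all* grid points instead is available as
`mode="all"`); one ground-truth instance per (image, class) with G > 0.
Correct when IoU ≥ 0.5. Detections sort by descending confidence with
incorrect-before-correct at ties — pessimistic and permutation-invariant.
AP integrates the monotone (right-to-left max) precision envelope over
recall; the 11-point interpolation is available behind a flag, the
envelope form is the default.

Report tables round to 3 decimals, half-up.

## Synthetic scenes

The generator emulates the structure of tongue photographs, not their
appearance: a dark noisy background, a pink elliptical tongue whose
normal mucosa carries a jittered bright-dot lattice (spacing 9 px, dot
radius 2 px — the papillae surrogate that drives the blob-density
feature), and abnormal patches (ellipses or rectangles, clipped to the
tongue; a patch wholly outside the tongue is an error) drawn with one of
six texture programs: smooth dark-red (papillary atrophy, erosion,
ulcer), dark sinuous grooves every 14 px (fissures), bright desaturated
plaque (hyperkeratotic and lichenoid change), heavy whitish speckle
(coating, hairy tongue), coarse dot lattice (papillary hypertrophy) and
bright specks (artifacts). Masks are exact by construction: other
outside the ellipse, abnormal exactly on patch footprints, normal
elsewhere inside. All randomness derives from one seed through
per-component spawn keys, so scenes are bitwise reproducible and
sub-components independently so.

The patch benchmark tiles random scenes with a non-overlapping 96 × 96
grid, labels each crop by the plurality rule, and keeps only
texture-pure crops (≥ 80% of the footprint in the plurality class) until
every class has its quota; mixed boundary crops are not single-texture
examples of any class, and the benchmark's purpose is a controlled
class-separability floor. The default study scale is 200 patches per
class, on which the texture baseline reaches ≥ 0.95 held-out accuracy
(measured ≈ 0.97–0.98) — the floor that makes downstream end-to-end
checks meaningful — and the small CNN, trained on a 480/120 split for 10
epochs, exceeds 0.90 validation accuracy (measured ≈ 0.99). The fixture
suite adds degenerate scenes (all-normal, all-abnormal, half/half split,
checkerboard, no-tongue) for end-to-end identities.

What passing these tests does **not** show: robustness to real papillary
texture variation, lighting, flash reflections, saliva bubbles, motion
blur, inter-patient variation, or genuinely ambiguous transition zones.
The synthetic classes are separable by construction; clinical
performance claims require clinical data.

## Numerical and design choices

* Crop-dimension rounding is half-up; overlapping-grid origins round
  half-up; both documented above.
* Resize is bilinear (`order=1`, no anti-aliasing) with a bitwise
  identity short-circuit at 96 × 96.
* Plurality (not majority) region labeling with the fixed
  ABNORMAL > NORMAL > OTHER tie order.
* Dots anchor at crop centers (the symmetric choice); ground-truth point
  labels summarize the full crop footprint, matching the classifier's
  support.
* The published clinical tables bundled in `tonguemap.reference` carry
  two internal quirks, preserved as printed: the test confusion matrix
  sums to 1228 while the split table lists 1229 test patches, and the
  listed training percentage (68.8%) is a truncation of
  5358/7782 = 68.851%. All per-class metrics derive exactly from the
  matrix as printed.
* Batch size (32) and the absence of early stopping are package
  defaults, not externally fixed values.

## Problem sizes

Default experiment sizes are desk-scale by design: 600-patch benchmarks,
576 × 864 scenes, 10-epoch CNN fits for reproducibility checks (the
50-epoch default applies to real training runs). These sizes are the
package's standard study conditions and are what the test suite and
`scripts/acceptance.py` execute.

## Known limitations

* The numpy CNN is single-threaded-CPU oriented; it is a reference
  trainable backend, not a performance implementation.
* Only one annotation per image is supported (no inter-rater modeling).
* Bit-level training reproducibility holds within one process/BLAS
  configuration; across BLAS builds, floating-point reduction order may
  differ.
* The boundary filter at its default threshold is nearly inert (see
  above); it exists as a hook, not as default curation.
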
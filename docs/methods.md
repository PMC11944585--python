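# Methods

## Problem

Filamentous fungi grown in pure culture on a standardized medium develop
colony colour patterns — pigment palettes — that are characteristic of the
species.  `chromoplate` implements an identification pipeline that exploits
this: a photograph of a Petri dish is searched for the circular plate, the
plate region is cropped and resized, and a convolutional network maps the
colour pattern to species probabilities.  The pipeline is evaluated with a
stratified 70/30 split, 5-fold cross-validation, per-species one-vs-rest
metrics, and ROC-AUC.  Because no public image collection accompanies this
kind of assay, the package ships a seeded synthetic plate-photograph
generator with known ground truth, and every quantitative claim in the test
suite is made against that ground truth.

## Synthetic plate model

An image is a light (205) or dark (40) background carrying one plate of
radius r at centre (cx, cy): an agar-toned disc, a thin (3 px) bright
plastic rim at the boundary, and a colony disc of radius 0.88 r.  The
colony colour grades linearly in normalised radius t from a centre tone
`center_rgb` (t = 0) to a peripheral tone `ring_rgb` (t = 1), mimicking the
concentric zoning of *Aspergillus*- and *Penicillium*-like colonies.  Two
noise processes are added: seeded low-frequency mottling (a Gaussian random
field with correlation length `texture_scale`, default 24 px, scaled to
per-channel sd `color_sd`, default 12) on the colony, and iid per-pixel
Gaussian sensor noise (`noise_sd`, default 6, band of interest up to 10)
everywhere, clipped to [0, 255].

Species palettes are rejection-sampled in RGB space with a pairwise
Euclidean floor of 60 units between centre colours, which makes classes
separable by colour alone — the property the real assay relies on.  The
area-weighted mean colour of a colony disc is `center/3 + 2·ring/3`
(∫₀¹ 2t[(1−t)c + t·g] dt), which the tests use as a Monte-Carlo oracle.

Defaults: canvas 512×512 (desk scale, not the 12–50 MP of phone
photographs; the detector's parameters scale with the radius bounds), plate
radius uniform in [80, 200] px, random position fully inside the frame,
background light/dark with probability ½ each.  The default dataset is 4
species × 30 images; a 10 × 27 layout reproduces the ~270-image scale of a
realistic single-lab study.  What the generator does **not** model:
perspective/ellipse distortion, specular highlights, shadows, multiple
plates per frame (except in tests that compose them), developmental
morphology beyond radius variation, or JPEG artefacts.  Passing tests
therefore demonstrate correctness of the pipeline's mechanics and its
behaviour under the stated noise model, not field performance on real
photographs.

## Plate detection

1. Per-channel Gaussian blur (kernel 9, σ = 2; truncation chosen so the
   kernel footprint matches the requested size).
2. Per-channel 3×3 Sobel gradients; magnitude per channel; channels
   combined by root-sum-of-squares so an edge present in a single channel
   still responds (the RSS choice is rotationally symmetric and unbiased
   across channels; `max` would also work but privileges single channels).
3. Min–max normalisation to [0, 255]; a constant image maps to all zeros.
   Normalisation is idempotent.
4. Circle Hough transform: pixels with edge response ≥ `param1` (default
   100) vote over radii in [`minRadius`, `maxRadius`] (defaults min_dim/8
   and min_dim/2); a circle's score is its raw vote count (the normalised
   accumulator times 2πr) and must reach `param2` (default 50) votes.
   Radius step is 1 px for windows ≤ 40 px and 2 px otherwise — well
   inside the ±5 px acceptance band.  Candidates are kept as local maxima
   (5×5) per radius plane, sorted vote-descending, and greedily suppressed
   so no two centres are closer than `minDist` (default min_dim/4).
   `dp` > 1 coarsens the accumulator by smooth-downscaling the magnitude
   map before thresholding; binarising first would alias the thin rim into
   a dashed ring and bias the radius.
5. Best circle = highest vote count among circles fully inside the frame;
   ties broken by larger radius, then smaller (cy, cx).  The winning
   circle's axis-aligned bounding square is cropped (clamped to the frame)
   and resized bilinearly.

Measured on the generator's conditions (noise sd 10): 100/100 plates
recovered within ±5 px of centre and radius at dp = 1; centres are stable
to ~1 px.  The batch pipeline (CLI train/evaluate/test) runs detection at
dp = 2, which is several-fold faster; its centre accuracy is unchanged and
an occasional radius lock onto the colony boundary (0.88 r) still yields a
well-centred crop for classification.

## Classifier

The default backbone (`small_cnn`) is three conv(3×3)/ReLU/max-pool blocks
with 16, 32, 64 filters, followed by global average pooling, a 64-unit
ReLU dense layer, and a softmax output — about 30 k parameters, trainable
in seconds per epoch on one core at 64×64 input.  A `vgg16` backbone
(the standard 13-convolution topology, 224×224 default input, optionally
frozen so only the head trains) is selectable for users who want the
heavyweight architecture; it is randomly initialised (He), as the package
ships no pretrained weights.  Inputs in [0, 1] pass through a fixed
centring layer to [−1, 1]; zero-centred inputs measurably speed up
convergence of the ReLU stack within the 25-epoch budget.

Training: Adam (lr 10⁻³, β = 0.9/0.999), batch 16, cross-entropy, 25
epochs by default.  Each mini-batch is augmented with label-preserving
transforms — rotation ±20°, shifts ±10 %, zoom ±10 %, horizontal and
vertical flips, brightness ±10 % — applied as one resampled affine map per
image plus a multiplicative brightness factor.  A stratified 20 % of the
training data is held out for validation (at least one image per class);
validation loss is monitored every epoch, training stops early after
`early_stopping_patience` epochs without improvement, and the weights with
the lowest validation loss are restored (and written to HDF5 if a
checkpoint path is set).  One integer seed drives weight initialisation,
the validation split, batch shuffling, and augmentation sampling; runs are
bit-reproducible.

Models persist as HDF5 containers holding the architecture descriptor
(JSON), all weight tensors, the class-label list, and the configuration;
save→load round-trips preserve predictions to < 10⁻⁶.

## Evaluation protocol

* **70/30 split** — stratified per class: round(0.7 n_c) training images
  per class, deterministic under the seed, disjoint by construction.
* **k-fold CV** (default k = 5) — items are shuffled within each class and
  dealt round-robin across the concatenated class blocks, so fold sizes
  differ by at most one (269 items → 54/54/54/54/53) and every class is
  spread as evenly as possible over folds.  Classes smaller than k trigger
  a warning (they cannot reach every test fold).  Each fold trains a fresh
  seeded model on the other k−1 folds and stores the full softmax vector
  for every test image; a failed run is recorded without aborting the
  rest.  Every image is classified exactly once across the k test folds.
* **Confusion matrix** — rows are predicted species, columns actual
  (the transpose of the sklearn convention); summing per-run matrices
  equals pooling the predictions.  The heatmap is column-normalised with
  "count (pct%)" annotations.
* **Per-species metrics** from the one-vs-rest 2×2 table (tp = diagonal
  cell, fn = rest of the actual column, fp = rest of the predicted row,
  tn = remainder):
  sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N,
  PPV TP/(TP+FP), NPV TN/(TN+FN), F1 = 2·PPV·Se/(PPV+Se),
  MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
  A zero denominator makes that metric *undefined* — reported as missing,
  never coerced to 0 — and averages skip missing entries with a warning.
  The summary table appends an **unweighted** mean row over species
  (support-weighted averaging would change the bottom line; the unweighted
  convention matches the published benchmark the tests pin against).
  Reported values are rounded half-up to 2 decimal places.
* **ROC/AUC** — one-vs-rest per species on the predictions pooled across
  all runs (pooling, rather than averaging per-run curves, is the simplest
  reading of a single curve per species); AUC is the trapezoidal area,
  which equals the Mann–Whitney pair statistic with ties counted ½ — the
  tests verify this against exhaustive pair enumeration.
* **Benchmark table consistency** — `reconstruct_counts` searches integer
  (TP, FN, FP, TN) reproducing all seven printed values of a metric row at
  2 dp; every row of the bundled ten-species benchmark admits such counts,
  and the recovered counts reproduce the printed MCC.

## Numerical and design choices

* Coordinates are 0-based pixels, x rightward, y downward; circle
  membership is Euclidean distance ≤ r inclusive.
* Rounding of reported metrics is decimal half-up (banker's rounding flips
  half-ulp cases the printed tables resolve upward).
* The F1-from-printed-rates identity is checked at ±0.01: the printed
  inputs are themselves rounded to 2 dp, so a half-ulp of slack propagates
  (one benchmark row sits exactly on a 0.005 boundary).
* Degenerate inputs: constant images give empty detections (not errors);
  a dataset class with < 2 images cannot be split and is rejected;
  undefined metrics propagate as missing values.
* Tie-breaks (best circle, argmax label) are fully specified so results
  are reproducible across platforms.

## Problem sizes used by the test suite and acceptance script

Detection recovery uses 100 plates at 512×512 with sensor noise sd 10 and
radius bounds [70, 210]; classification recovery uses the 4 × 30 dataset at
64×64 with 25 epochs (three seeds for the split experiment, five folds for
CV); oracle fuzzing uses 1000 confusion matrices and 200 score sets of at
most 50 items.  These sizes give stable pass/fail behaviour at desk scale;
all of them are parameters, not limits of the implementation.

## Known limitations

* The synthetic generator's realism gap (above) means measured accuracies
  characterise the pipeline, not field performance on real photographs.
* The Hough search assumes near-circular, fully visible plates; off-axis
  (elliptical) dishes and partially out-of-frame plates are out of scope.
* The `vgg16` backbone is practical only for inference-scale experiments
  on CPU; training it end-to-end at 224×224 is far slower than the
  default backbone and is not exercised by the test suite.
* With very small classes (< k images) stratification degrades gracefully
  but per-class metrics on such classes are noisy and may be undefined.
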
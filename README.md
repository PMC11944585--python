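# chromoplate

Fungal colony identification from culture-plate photographs by
**chromogenic profiling** — the species-specific colour palettes that
fungal colonies develop when grown on a standardized medium.

Many culturable fungi (*Aspergillus*, *Penicillium*, *Alternaria*,
*Fusarium*, …) deposit characteristic pigments; on a uniform agar the
colony's centre/ring colour pattern is a usable taxonomic signal that a
camera can capture far faster than molecular identification can run.
`chromoplate` turns a top-down photograph of a Petri dish into a species
call in three stages:

1. **Plate detection.**  Gaussian blur → per-channel Sobel gradients →
   root-sum-of-squares magnitude, min–max normalised to [0, 255] → circle
   Hough transform over (centre, radius) space, governed by the familiar
   `dp / minDist / param1 / param2 / minRadius / maxRadius` parameters.
   The best-fitting circle fully inside the frame is cropped and resized.
2. **Classification.**  A convolutional network (conv/pool blocks →
   global average pooling → dense → softmax) maps the crop to per-species
   probabilities ŷ = softmax(f(x)); training uses label-preserving
   augmentation, early stopping on validation loss, and checkpointing of
   the best weights.  Models persist as HDF5 with their label list.
3. **Evaluation.**  Stratified 70/30 split and k-fold cross-validation
   (default k = 5, 25 epochs per run); aggregate confusion matrix (rows =
   predicted, columns = actual); per-species one-vs-rest metrics —
   sensitivity, specificity, accuracy, PPV, NPV, F1 = 2·PPV·Se/(PPV+Se),
   and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) — with an
   unweighted average row; one-vs-rest ROC curves whose trapezoidal AUC
   equals the Mann–Whitney pair statistic.

Because no public plate-photo collection exists for this assay, the
package includes a seeded **synthetic plate generator** (species palettes
with a configurable RGB distance floor, radial centre→ring colour
gradients, mottling, plate rim, light/dark backgrounds, sensor noise)
whose ground-truth geometry and labels back every quantitative test.
See `docs/methods.md` for the full model and its assumptions.

Intended users: mycology / clinical-microbiology labs prototyping
image-based colony triage, and anyone needing a fully reproducible,
dependency-light reference implementation of the detect–classify–evaluate
protocol.

## Worked example

```sh
$ chromoplate simulate --species 3 --per-species 8 --out plates --seed 42 --quiet
24 images, 3 species, manifest plates/manifest.csv

$ chromoplate train --dataset plates --out run --epochs 10 --batch-size 8 --seed 42 --quiet
model run/model.h5
history run/history.csv (10 epochs, final accuracy 1.0000)

$ chromoplate test --model run/model.h5 --input plates/species_A --out report --quiet
8 images classified, report report/classification_report.csv

$ head -3 report/classification_report.csv
path,flag,predicted_label,p_species_A,p_species_B,p_species_C
plates/species_A/species_A_000.png,ok,species_A,0.971982,0.018230,0.009789
plates/species_A/species_A_001.png,ok,species_A,0.972791,0.017967,0.009242
```

`simulate` writes one subdirectory per species plus a manifest with each
plate's true centre/radius/seed.  `train` detects and crops the plate in
every image, fits the CNN (here to perfect training accuracy on an easy
3-colour problem), and saves the HDF5 model.  `test` reports, per image,
the detected plate's species call and the full probability vector — a row
is flagged `no_plate_detected` (and the run continues) when no circle
passes the vote threshold.  `chromoplate evaluate --dataset plates --out
eval` runs the whole cross-validation protocol and writes the metrics
table, confusion heatmap, training curves, ROC plot, and per-image
predictions.  All commands accept `--seed` and rerun bit-identically.

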
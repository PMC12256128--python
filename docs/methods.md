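# Methods

## The audit model

The package treats mislabel detection as a resampling-ensemble problem. A
specimen catalog assigns each image a *current* label, which is the label
under audit — it is never treated as ground truth, only as the class
definition for training and the reference against which predictions are
compared. The pipeline repeats, `n_runs` times:

1. **Sample.** Per class, draw `sample_n` specimens without replacement
   (`train_n` for training, `val_n` for validation) with seed
   `base_seed + run_id`. Everything else forms that run's test pool.
2. **Train.** Fit the classifier from the same initial weights every run
   (`model_init_seed` is constant across runs; only the sampled subset
   changes). Training and validation images are each augmented `aug_copies`
   times, originals kept.
3. **Score.** Predict every test-pool image; record the argmax label, its
   confidence, and whether it matches the current label.

Per specimen, the runs whose test pool contained it are its *eligible* runs.
The **reoccurring prediction value (RPV)** is the count of eligible runs
that assigned the specimen its modal mispredicted label. The definition is
stated in the literature only for the case where every misprediction agrees;
we generalise to the modal label with an explicit `consistent` flag so that
specimens with disagreeing mispredictions remain representable in reports
rather than being dropped. For a specimen with no mispredictions, RPV is 0,
the modal label is empty and `consistent` is vacuously true. Ties between
modal candidates break to the lexicographically smallest label (and mark the
record inconsistent). Because eligibility varies per specimen with the
sampling, `rpv / eligible_runs` is exported alongside the raw count and is
the recommended ranking statistic; the raw count is what historic reports
print.

Two aggregation routes exist deliberately: the production path
(`compute_rpv`, vectorised over a DataFrame) and a naive dict-loop recount
(`brute_force_rpv`) kept as an independent oracle; tests assert their exact
equality on randomized logs.

## Training protocol

Two-phase transfer training, mirroring frozen-backbone fine-tuning:

* **Phase 1** trains only the classification head for exactly
  `phase1_epochs` (default 5) with every backbone layer frozen.
* **Phase 2** unfreezes all layers except the bottom `frozen_bottom_layers`
  and fine-tunes with a fresh optimiser state. After each epoch the
  validation accuracy is compared with the phase-2 running best: the first
  epoch that fails to improve it stops training (patience 1, the semantics
  of the usual `EarlyStopping(patience=1)` callback — a tie counts as no
  improvement, which also bounds runtime when accuracy plateaus at 1.0 on
  separable data). A `max_epochs` cap (default 100) bounds the phase when
  accuracy keeps improving.
* The weights of the globally best epoch (earliest on ties, across both
  phases) are restored at the end.

The early-stopping monitor is scoped to phase 2 because the first epochs
after unfreezing routinely dip below the head-only accuracy; comparing
against the phase-1 best would otherwise stop fine-tuning immediately.

The backbone is pluggable through `BackboneSpec` (layer count, frozen
bottom count, input size). The default desk-scale backbone is a small
fully-connected ReLU network (`network.DenseNet`: input → 128 → 64 → softmax
head) trained with Adam (lr 3e-3, batch 32) on images resized to 32×32×3 and
scaled to [0, 1]. Dense layers were chosen over small convolutions purely
for CPU speed at this input size; the freeze/early-stop/restore semantics —
the part of the protocol the audit depends on — are identical. All
arithmetic is float64 and all randomness flows through seeded
`numpy.random.Generator`s, so two fits with the same seeds and data are
bit-identical, and two pipeline executions with the same config produce
byte-identical CSV outputs.

A large pretrained convolutional backbone (the configuration used for
full-collection audits) slots in behind the same `BackboneSpec` contract;
hyperparameter search is out of scope — head hyperparameters are fixed,
configurable, and recorded in the run manifest.

## Preprocessing

* **Cropping.** Uncropped specimen photographs contain labels and scale
  bars that attract model attention. Each image is cropped to the
  highest-confidence detection, expanded by `crop_margin` (default 0.05)
  per side and clipped to the image; ties between detections break by
  larger area, then top-left position. If detection fails the full image is
  used and the provenance record carries `fallback=true`. The detector is a
  contract (`image -> [(box, confidence)]`); the built-in
  `default_detector` takes the largest connected non-background component
  (background = modal border colour, per-channel tolerance 12) with
  confidence = component area / image area, which is exact on synthetic
  renders and on any uniform-background imaging rig. A trained object
  detector can be dropped in for field imagery.
* **Size is deliberately discarded.** Cropped images are resized to the
  model's square input, so absolute specimen size cannot inform the
  classifier. This reproduces a known limitation of image-only audits:
  species pairs distinguished mainly by size will generate flags that
  experts must resolve with the scale bar or locality data.
* **Augmentation.** Each copy applies one random rotation (uniform ±15°),
  zoom (uniform [0.9, 1.1]) and brightness multiplier (uniform [1.0, 1.2] —
  "slight brightening", increase only), with rotation gaps filled with the
  modal border colour. Ranges are configurable; outputs keep the input size
  and the valid [0, 255] range.
* **Attention QC.** `attention_on_specimen_fraction` measures the share of
  a non-negative saliency map inside the specimen box. The saliency method
  is a pluggable hook; the built-in `SmallImageClassifier.saliency_map` is
  plain input-gradient magnitude. The integration test reproduces the
  motivating observation: classifiers trained on cropped images concentrate
  substantially more saliency mass on the specimen than classifiers trained
  on uncropped, label-bearing images.

## Synthetic data: what it emulates, what it does not

`synthetic` renders stylised specimens — two mirrored wing ellipses plus a
body on a uniform board, with a sinusoidal stripe texture — whose class
identity is carried by four parameters: body hue, stripe frequency
(cycles per image width), wing aspect and nominal scale (fraction of the
canvas). Per-specimen jitter is fixed in a documented constants block:
rotation ±5°, size ±10%, hue ±5°, centre ±3%. An optional text-like label
strip is drawn below the specimen (always outside its bounding box) to give
the cropping stage something real to remove. The exact foreground bounding
box is returned with each render, giving the detector an exact oracle.

**Identifiability rule for confusable pairs.** A confusable partner reuses
its mate's parameters shifted by small deltas. Each delta must exceed the
ambiguity band induced by that parameter's per-specimen jitter, otherwise
partner classes overlap and no classifier could separate them, while
remaining far below the spacing of non-confusable species:

* hue delta **+12°** against a ±5° jitter (supports disjoint by 2°; hues of
  non-confusable species are evenly spaced ≥ 45–60° apart);
* stripe delta **+1.0 cycle** against the ~±10% apparent-frequency noise
  that size jitter induces after crop-and-resize (stripe levels of
  non-confusable species are evenly spaced over [3, 7]).

Wing aspect and scale are identical within a pair — and crop-plus-resize
destroys most of their signal anyway, which is intended: it reproduces the
size-blindness limitation above.

Label swaps are injected by drawing `round(rate · total)` specimens without
replacement; a swap goes to the confusable partner with probability 0.8
(else uniformly to another class), mimicking the realistic case where
mislabels land on morphologically similar species.

What the generator does **not** emulate: photographic nuisance (lighting
gradients, blur, pose variation beyond rotation), damaged or faded
specimens, pins and scale bars beyond the one label strip, within-species
polymorphism, and class imbalance. Passing tests therefore demonstrate that
the *method* — resampled training, RPV aggregation, triage reporting — is
implemented correctly and recovers known swaps under controlled separability;
they do not certify recall on real collections, where class confusability
and label-noise structure are unknown.

## Reference study conditions (`study.py`)

The recovery experiment is fixed at: 6 species with 2 confusable pairs, 80
images per species, 3% injected mislabels, 20 runs, per-run sampling 40
(30 train / 10 validation) per class. Sampling half of each class per run
leaves each specimen test-eligible in ~10 of 20 runs, so the ratio
statistic has ~0.1 resolution. Outcomes reported: ROC-AUC of
`rpv/eligible_runs` against the injected indicator, and precision/recall of
flagging at ratio ≥ 0.8 (the desk-scale analogue of "flagged in more than
80% of runs"). Five seeded replicates (fresh species set, dataset and
sampling seeds; shared model-init seed) quantify run-to-run variability.

## Reporting conventions

* Interval tables tile [1, n_runs] in inclusive width-10 bins rendered
  zero-padded ("01–10" … "91–100"), highest interval first; percentages are
  of the flagged total (RPV ≥ 1), rounded half-up to 2 decimals via
  `Decimal` so printed values never depend on binary-float artefacts. An
  override denominator exists for reproducing historic tables whose stated
  totals differ from their column sums.
* The flag list uses a strict inequality (`rpv > threshold`) and a stable
  sort (rpv descending, then specimen id).
* Expert verdicts (`labelled_wrong`, `pipeline_wrong`, `portal_wrong`,
  `unknown`) and visual-difficulty scores (1–4; 4 = impossible visually,
  referred to genetic verification) are closed vocabularies; free-text
  notes are never parsed. Summary functions only ever report sums of their
  input records — no historic totals are built in.
* Genetic reconciliation outcomes are `confirms_pipeline_wrong` (the
  barcode supports the catalog label, i.e. the classifier was wrong) and
  `contradicts_both` (the barcode disagrees with both the catalog label and
  the visual assessment).

## Degenerate inputs and numerical choices

* A saliency map summing to zero yields attention fraction 0 by definition.
* `interval_table` on zero flagged specimens warns and returns an empty
  table; `filter_classes` that removes every class raises an error carrying
  the observed per-class counts.
* Augmentation with non-degenerate ranges asserts novelty only
  statistically (copies are not byte-equal to the original); a zero-range
  config legitimately returns near-copies.
* `desk_scale_config` sets the class filter to 60 (below the nominal 80 per
  species) so classes whose current-label counts shift by a few injected
  swaps are not silently dropped, and a count flag threshold of 8 ≈ 80% of
  the typical 10-run eligibility.
* Non-finite training loss aborts with the epoch index; single-class
  training sets and validation labels unseen in training are rejected up
  front.

## Known limitations

* The dense desk-scale backbone saturates around 32×32 inputs; species
  separated only by textures finer than that resolution need a larger input
  size or a convolutional backbone.
* RPV is a ranking statistic, not a calibrated mislabel probability; no
  noise-matrix estimation or posterior calibration is attempted.
* Specimens sampled into train/val in every run have no eligible runs and
  cannot be audited (vanishingly rare at study sampling fractions, but the
  eligible-run count in the output makes such rows visible).
* Low-RPV flags are dominated by classifier noise — in the full-scale study
  more than 80% of flagged specimens sat in the lowest interval — so triage
  effort should start from the top of the ranked list.
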
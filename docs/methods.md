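# Methods

## Model and procedure

`slideuq` operationalises selective classification for tile-based
binary slide diagnosis. The object of inference is not the classifier
itself (which is supplied, or simulated) but three operating
thresholds estimated from labelled training data:

1. **Tile uncertainty threshold θ_tile.** Each tile's uncertainty is
   the population standard deviation of its `J` dropout forward
   passes. Uncertainty is treated as a diagnostic test for
   misprediction: at a candidate cutpoint `t`, sensitivity is the
   fraction of mispredicted tiles with `σ̂ ≥ t` and specificity the
   fraction of correct tiles with `σ̂ < t`. θ_tile maximises Youden's
   `J = Se + Sp − 1`. Tiles strictly below θ_tile are high-confidence.
2. **Slide uncertainty threshold θ_slide.** Slide uncertainty is the
   mean σ̂ over the slide's high-confidence tiles and the slide
   prediction the mean μ̂ over the same set; θ_slide is found by the
   identical Youden construction on slides, with slide correctness
   taken at the interim 0.5 cutoff (the prediction threshold does not
   exist yet at that stage).
3. **Prediction threshold θ_pred.** A standard ROC Youden optimum for
   classifying label 1 by `μ̂(x_slide) ≥ t` on validation-style data.

Because steps 1–2 consume ground-truth labels, estimating them on the
data used to report performance would leak. The nested protocol
therefore splits each outer training set into `k_inner = 5`
stratified folds, derives one (θ_tile, θ_slide) pair per fold from a
predictor fitted on the other inner folds, and combines them as
**min** over folds for θ_tile and **max** for θ_slide. The asymmetry
is implemented as specified by the protocol and not reinterpreted;
both choices are conservative in the sense of retaining fewer
high-confidence tiles and more low-confidence slides. θ_pred is
computed per bootstrap repeat on the pooled outer-validation slide
predictions of that repeat — pooling uses every slide exactly once and
yields a single threshold per repeat.

Assumptions worth stating explicitly:

* predictions live on [0, 1], so σ̂ is bounded by 0.5;
* a slide maps to exactly one label and one patient; tiles inherit
  their slide's label (weak supervision);
* uncertainty is informative about correctness — mispredicted tiles
  are noisier across passes than correct ones. All guarantees
  (J = 1 at perfect separation, improvement of the high-confidence
  cohort) degrade gracefully as this association weakens.

## Conventions and degenerate inputs

* **"All possible thresholds"** is realised as midpoints between
  consecutive distinct observed values plus one candidate below the
  minimum and one above the maximum. Se/Sp are step functions that
  change only at observed values, so a continuum scan cannot find a
  better J; the finite grid is exact. The outer candidates are placed
  multiplicatively (`min/2`, `max·1.5`, additive offset of 1 at zero)
  so that rescaling the inputs rescales every candidate.
* **Ties in J** resolve to the smallest candidate — the conservative
  side, flagging more items low-confidence.
* **Degenerate searches** (no mispredicted items, or no correct
  items) do not raise: they return `+inf` / `−inf` sentinel optima
  ("everything high-confidence" / "everything low-confidence") with a
  recorded reason, because inner folds on easy data hit these cases
  routinely. Degenerate folds are excluded from the min/max
  combination; if every fold is degenerate the combined threshold is
  the `+inf` sentinel with a loud warning.
* **Boundary semantics** are strict everywhere: high-confidence means
  `σ̂ < θ`; equality is low-confidence.
* **Slides with zero high-confidence tiles** leave the slide mean
  undefined. They fall back to the all-tile mean prediction, receive
  infinite uncertainty, are forced low-confidence, and carry a
  `fallback_used` flag — the clinical "abstain but still report"
  semantics. Inside the slide-level Youden search, infinite
  uncertainties are mapped to twice the largest finite value plus one:
  strictly above every real uncertainty, order-preserving, and finite
  as the search requires.
* **Tile class ties** (μ̂ exactly 0.5) classify as class 1; the
  cutoff convention is documented rather than consequential.
* **Constant ensembles** are assigned σ̂ = 0 exactly, avoiding the
  ~1e−16 rounding residue a naive mean-of-squares leaves.
* **AUROC** uses the midrank convention (ties count one half), equal
  to the probability a random positive outranks a random negative.
  Metrics on empty or single-class cohorts report null values with the
  cohort still present in the report, never a silent drop.

## Synthetic data generator

The simulator emulates, on the probability scale, the ensemble
structure of a well-trained dropout classifier:

| parameter | default | meaning |
| --- | --- | --- |
| `n_slides_per_class` | 200 | ordinary slides per class |
| `tiles_per_slide` | 200 | tiles per slide |
| `passes` | 30 | forward passes J per ensemble |
| `clear_center_offset` | 0.15 | clear-tile mean distance from its class pole |
| `clear_pass_sd` | 0.05 | pass-to-pass spread of clear tiles |
| `ambiguous_pass_sd` | 0.25 | spread of ambiguous tiles (must exceed clear) |
| `ambiguous_center_sd` | 0.08 | jitter of ambiguous-tile centres around 0.5 |
| `ambiguous_tile_fraction` | 0.10 | ambiguous tiles per ordinary slide |
| `intermediate_slide_fraction` | 0.10 | pure-ambiguous random-label slides |
| `class_ratio` | 1:1 | ordinary-slide class ratio (1:3, 1:10 supported) |
| `multi_slide_patient_fraction` | 0.0 | slides merged into shared patients |

Pass values are clipped Gaussians: clear tiles centred at
`pole ± 0.15` with σ 0.05, ambiguous tiles at a per-tile centre
jittered around 0.5 with σ 0.25. Clipping to [0, 1] shrinks moments
near the poles slightly; tests use tolerance bands accordingly.
Intermediate slides consist purely of ambiguous tiles and carry
uniformly random labels — the decision-boundary stress case. The
default 10% intermediate fraction gives the validation sets a
realistic abstention workload (roughly 80–95% of slides end up
high-confidence, matching the rates typical of real validation
cohorts) and guarantees the slide-level threshold search has genuine
positives; sizes are desk-scale so a full bootstrapped experiment runs
in seconds, not the thousand-slide scale of production corpora.

What the generator does **not** model: spatial correlation between
neighbouring tiles, site/scanner batch effects, label noise on
ordinary slides, heavy-tailed or multimodal pass distributions, and
any pixel-level realism. Passing tests therefore demonstrate the
correctness and internal guarantees of the thresholding machinery
under its stated assumptions — not clinical performance.

The **oracle predictor** backs the nested-CV predictor contract with
the generator's latent state: `fit` records the training-set size and
`predict_ensemble` regenerates ensembles from each tile's latent
centre/spread and the contract seed. Deviations are drawn once in the
dataset's canonical tile order, making ensembles independent of how
tiles are batched into folds. An optional degradation exponent widens
spreads as the training set shrinks, giving folds authentic variation.

## Demo classifier

The end-to-end demo trains a two-hidden-layer perceptron (width 64,
ReLU, sigmoid output) written directly in numpy, with inverted dropout
(p = 0.1) after each hidden layer kept active at inference; repeated
stochastic forward passes yield genuine MC-dropout ensembles. Inputs
are procedurally generated 64×64 texture tiles (class 0: soft random
blobs; class 1: oriented stripe gratings; an ambiguity level blends
the motifs). The module demonstrates the mechanism on a CPU in
seconds and makes no performance claims.

## Design choices that were genuinely open

* **Model front-end.** The threshold estimation is exposed as a
  statsmodels-style pair — `UncertaintyThresholdModel.fit()` returning
  `ThresholdResults` with estimates, per-fold provenance, search
  diagnostics and `summary()` — on top of the functional modules. The
  model's `method="nested"` variant partitions slides and reuses the
  supplied ensembles per fold (appropriate when refitting a predictor
  is impossible); the fully refitting protocol lives in
  `slideuq.nested_cv` behind the predictor contract.
* **Patient aggregation** pools tiles, not slide predictions: all of a
  patient's tiles form one super-slide which is aggregated with the
  slide machinery. Slides with more tiles therefore weigh more.
* **Class-ratio subsampling** keeps the majority class at the
  available count and scales the minority (floor rounding), leaving
  intermediate slides untouched.
* **Fold plans** are keyed by sorted slide identifiers and seeded, so
  input order never changes membership; stratification is exact to ±1
  per class via stratified k-fold, with group-aware splitting engaged
  whenever multi-slide patients are present (a patient never straddles
  a fold boundary; exact stratification is then best-effort).
* **Serialisation** uses 17-significant-digit floats, round-trip
  parsing, sorted-key JSON, and provenance records without wall-clock
  fields, so every artifact is byte-reproducible from config + seed;
  threshold sentinels serialise as the strings `"inf"` / `"-inf"`.

## Problem sizes used in tests

Unit tests run on datasets of 20–60 slides with 10–50 tiles. The
experiment-level checks use the default study conditions above
(200 slides/class × 200 tiles × 30 passes; 3-fold outer CV
bootstrapped twice with 5 inner folds), repeated over 20 seeds for the
cohort-improvement check and once with 50% intermediate contamination
for the rejection check. Reported quantities are always recomputed at
run time; nothing is cached between runs.

## Known limitations

* Binary outcomes only; multi-class and regression uncertainty are out
  of scope, as are entropy-, ensemble- and augmentation-based
  uncertainty estimators.
* Youden-optimal cutpoints weigh sensitivity and specificity equally;
  no cost-weighted operating points.
* The slide-level search sees capped surrogates for infinite
  (fallback) uncertainties; a different cap cannot change which slides
  are separable but can move the reported θ_slide when the optimum
  lies at the fallback boundary.
* Confidence intervals on cohort metrics are not computed; per-fold
  tables are emitted so users can bootstrap externally.
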
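# Methods

This note documents the models, conventions and numerical choices behind
`tkrisk`, and what the synthetic experiments do and do not establish.

## Pipeline overview

A visit-level record consists of a 3D knee MRI volume, a co-registered
integer-labeled tissue atlas, a Kellgren–Lawrence (KL) grade, the time of a
first total knee replacement (TKR) if any, and 27 clinical/demographic
variables. The pipeline labels visits (case ⇔ first TKR within 5 years,
closed interval), splits patients 65/20/15 into train/validation/test with
all visits of a patient in one split, balances the rare TKR class 1:1 by
bootstrap resampling, imputes missing clinical values by k-nearest
neighbors (k = 5, Euclidean distance on standardized columns over mutually
observed entries), trains a convolutional risk classifier on quantized
volumes, fuses its scalar output with the 27 variables through
OA-stratified logistic ensembles, and finally interrogates the fitted
pipeline with occlusion maps to produce a per-tissue odds-ratio table.

## Preprocessing

Volumes are center-cropped (the odd margin's smaller half goes on the
low-index side) and quantized by per-volume min–max scaling to
[0, n_levels − 1] followed by rounding. Choices:

- *Scaling scope.* Per-volume rather than per-dataset: it is the simplest
  scheme whose rounding yields exactly `n_levels` values on any volume with
  a well-populated range, and it needs no dataset-level state.
- *Rounding.* Half away from zero (not banker's rounding), so level
  boundaries are platform-independent and the map is monotone and
  idempotent.
- *Constant volumes* map to all zeros by convention.

## Risk classifier

The classifier is a densely connected convolutional network: initial
strided convolution → batch norm → leaky ReLU → 2× average pooling; four
dense blocks of bottlenecked composite layers (BN → LReLU → 1×1 conv to
4 × growth channels → BN → LReLU → 3×3 conv to growth channels → dropout)
joined by channel concatenation, with halving transitions between blocks;
then BN → LReLU → global average pooling → a 2-class linear head. The
reference configuration is 16 initial filters, growth 32, blocks
[6, 12, 24, 16]; the desk preset (8 filters, growth 8, blocks [2, 4, 4, 2],
3³ initial kernel) handles 24 × 48 × 48 volumes in minutes on one CPU.

The sub-package `tkrisk.nn` implements the layers directly in NumPy
(channels-last float32, convolution as a sum of per-kernel-offset strided
matrix products, hand-written backward passes, Adam). Gradients are
verified against central finite differences in the test suite. Notable
conventions:

- *Pooling* is non-overlapping 2× average pooling with ceil-mode zero
  padding; edge cells divide by the true element count so they are
  unbiased. (The classical max-pool stem is replaced by average pooling to
  keep the backward pass simple; at these scales the difference is
  immaterial to the contracts tested.)
- *Loss* is class-weighted softmax cross-entropy, weights (w_TKR, w_control)
  summing to 1; (0.5, 0.5) equals half the unweighted loss.
- *Early stopping* evaluates validation loss after every epoch and stops
  after `patience` consecutive rises (default 1 — "stopped when validation
  loss began to increase"); the parameters of the best-validation-loss
  epoch are restored.
- *Freezing* enumerates parameterized layers in depth order; the
  classification head is exempt and always trainable.
- *OA pretraining* uses a binary KL ≥ 2 target, consistent with the fixed
  2-class head; graded pretraining is not attempted.
- *Random search* (25 iterations by default) samples learning rate
  log-uniformly on [1e-6, 1e-1], dropout uniformly on [0, 0.5], TKR class
  weight uniformly on [0.5, 0.99], and the freezing choice from
  {last-1, last-2, all-but-head}; candidates train on a seeded stratified
  subsample (`subset_fraction`) and are scored by the unweighted mean of
  validation accuracy, sensitivity and specificity, ties to the earlier
  iteration. Optimizer (Adam) and batch size are configuration, with the
  defaults above.

## Stratified ensembling

The 28-feature vector is [risk] ++ the 27 variables in a fixed canonical
order. `lr_random_search` fits 100 logistic candidates with class weight
w ~ U[0.5, 0.99] on standardized training features. The fit uses weak L2
regularization (C = 100): with the default C = 1, an extreme weight pair
like (0.99, 0.01) lets the penalty dominate the minority-class term and the
candidate collapses to the majority class even on widely separable data;
at C = 100 the searched weights, not the penalty, set each candidate's
operating point. Candidates are ranked per stratum by Youden's index at
threshold 0.5 on the stratum's validation records (threshold choice: the
natural probability cut, as no operating threshold is otherwise specified);
k is chosen in 1..8 by the mean of validation accuracy, AUC and J, ties to
the smaller k. Prediction averages the selected members' probabilities, so
it always lies within [min, max] of the members.

## Evaluation statistics

- AUC by trapezoidal integration over distinct score thresholds; with ties
  it equals the Mann–Whitney U statistic divided by n_pos · n_neg (asserted
  to 1e-12 against both a brute-force pair count and scipy).
- Bootstrap: B = 100 full-size resamples with replacement; degenerate
  (single-class) resamples are redrawn, at most 100 times, then an error.
  95% intervals are mean ± 1.96 sd (matching mean ± multiple-of-error
  reporting); percentile intervals are available behind a flag.
- McNemar without continuity correction (behind a flag), p from χ²(1);
  if p < 0.05 the direction is tested by the one-sided exact binomial
  probability of ≥ max(n01, n10) successes in n01 + n10 trials at rate ½.
- Paired-bootstrap AUC test: the two score vectors share each replicate's
  index draw; t = mean/(sd/√B) on B − 1 df, one-sided ("first argument
  greater"); identical score vectors give p = 1 by convention.

## Occlusion biomarkers

Occluder positions start at offset 0, advance by the stride per axis, and
must lie fully inside the volume; each voxel's map value is the mean |Δrisk|
over the positions covering it; uncovered voxels are excluded from ranking.
Conventions chosen where the procedure is underdetermined:

- *Fill value* 0 on the quantized scale (the background level); mean-fill
  behind a flag.
- *Magnitude* = absolute change; signed maps behind a flag.
- *Occluded scalar* = the integrated (ensemble) probability with the
  record's non-imaging features held fixed; image-only mode is available.
- *Hotspots* are thresholded per subject map (top 5% of ranked voxels,
  exactly ⌊0.05 · N⌋, ties broken by ascending linear voxel index).
- *Tissue flag*: a tissue counts as hotspot-positive for a subject when at
  least one hotspot voxel intersects its region; the threshold is
  configurable as an absolute count, a fraction of tissue volume, and/or a
  minimum occlusion response (`min_response`). The response floor exists
  because the top 5% is a *relative* cut: a subject whose classifier output
  barely reacts to any occlusion still has a top percentile, but those
  "hotspots" are noise, and — worse — a trained detector's own locations
  are its most *relatively* sensitive cells even in subjects without the
  finding, so purely relative flags can mark the signal tissues in
  everyone. Requiring the flagged voxel to have moved the predicted
  probability materially (the recovery study uses 0.05, i.e. five
  percentage points) restores the case/control magnitude contrast the
  odds ratio is meant to measure.
- *Matching* samples, per OA stratum, as many true-negative controls as
  cases without replacement and accepts the draw iff a paired t-test on
  KOOS pain across the n pairs (df = n − 1) does not reject at α = 0.05.
- *Cornfield interval*: exact conditional bounds from Fisher's noncentral
  hypergeometric model — the lower endpoint solves P(X ≥ a | ψ) = 0.025 and
  the upper P(X ≤ a | ψ) = 0.025 — by bracketed root-finding on log ψ
  (bracket ±40, relative tolerance 1e-12); lower endpoint 0 when a = 0 or
  d = 0, upper infinite when b = 0 or c = 0. Verified against direct
  noncentral-hypergeometric tail summation and scipy's conditional
  interval.
- *Fisher p*: point-probability method in exact integer arithmetic — the
  sum of hypergeometric probabilities of all tables (margins fixed) no more
  probable than the observed one.
- *Significance* requires both p < α and 1 outside the CI. Tissues whose OR
  is undefined (flagged in nobody, or in everybody) are emitted with a note
  rather than dropped.

## Synthetic cohort generator

The generator emulates the *statistical* structure the pipeline assumes,
not knee anatomy: ellipsoid/box "tissues" on a small grid; per-patient
visit times at integer years; per-patient KL trajectories drawn iid from
the configured KL distribution and sorted, so severity never regresses; a
per-visit case label drawn with the stratum's rate (defaults 0.004 / 0.039
/ 0.29 for no / moderate / severe OA, the reference cohort's test-split
prevalences); cases get a TKR at visit + U(0.5, 5) years, 10% of controls a
late event at visit + U(5.5, 12); KOOS pain from label-specific normals
(87.4 ± 16.5 controls, 68.7 ± 20.6 cases) clipped to [0, 100]; the other
26 variables from label-shifted Gaussians/Bernoullis whose parameters are
plausible stand-ins (only the variable names are given by the source
design, so these distributions must not be read as calibrated); and
independent per-cell missingness. Volumes are a per-tissue base anatomy
plus the configured case effect plus Gaussian voxel noise, fully
reproducible from the seed. Optional per-visit tissue-intensity jitter
(``tissue_jitter_sd``, default off) varies each tissue's brightness around
its nominal value, emulating anatomical variability across subjects;
without it, every subject shares literally identical anatomy, and a
trained classifier's small occlusion responses rank the same bystander
tissues in every subject's map — a degeneracy real cohorts do not have.

What passing tests on this cohort shows: the pipeline's operations satisfy
their contracts and the biomarker machinery recovers a known planted
signal. What it does not show: performance on real MRI, robustness to
registration error, scanner effects, correlated clinical covariates, or
anatomically realistic lesion shapes.

## The recovery study (desk scale)

`tkrisk.experiments.planted_biomarker_experiment` runs the whole pipeline
on ~340 patients (~650 visits) at 24 × 48 × 48 with ten ellipsoidal
tissues, each centered in a distinct occlusion cell, and the occluder
geometry scaled proportionally from the full-scale 12 × 32 × 32 / stride 12
(here 6 × 12 × 12 / stride (6, 12, 12), 64 positions, full coverage).
Design choices, made once for the study:

- *Case rates* are elevated ({none 0.15, moderate 0.30, severe 0.35}) over
  the observational defaults: at this scale the observational rates leave
  whole strata without a single case, making stratified ensembles
  unfittable, and matched pairs too few for any odds ratio to reach
  significance. The defaults of `PhantomSpec` keep the observational rates.
- *Heterogeneous lesions.* Each case carries the intensity shift (4× the
  voxel noise sd) in exactly **one** of the two biomarker tissues, chosen
  at random per case. With the shift planted in both tissues of every
  case, a classifier can separate the classes from either tissue alone and
  often shortcuts onto one, leaving the other invisible to occlusion — an
  instructive failure, but not a test of recovering two biomarkers.
  Per-case heterogeneity forces attention to both.
- *Contrast-free base with a bright anchor.* All tissues share the
  background's base intensity except one bright anchor tissue (the
  patellar tendon region, base 18 vs 8). Two degeneracies motivate this.
  First, with per-tissue brightness contrasts, a control's occlusion map
  ranks tissues by brightness — the classifier's shared convolutional
  features respond to any bright-to-fill content change — so the same
  bystander tissues are "hotspots" in every control and acquire spurious
  OR 0/∞ significance. A contrast-free base makes control hotspot
  placement noise-driven. Second, without any bright structure, the
  planted lesion would set the per-volume intensity maximum and thus leak
  into the global min–max quantization scale, letting the classifier read
  the label off the background level; the anchor pins the scale for cases
  and controls alike (it is itself flagged in essentially every subject,
  case and control, which leaves its odds ratio undefined and the tissue
  non-significant — the framework reports the row with a note).
- *Training budget*: up to 10 epochs at learning rate 2e-3, batch 16,
  patience 3, balanced by oversampling, weights (0.5, 0.5); OA pretraining
  is skipped here because the phantom places no KL-correlated signal in
  the images (pretraining is exercised by its own tests).
- *Occluder fill*: the study uses mean fill. A zero-filled block is so far
  outside the training distribution of these phantoms that the classifier's
  output on it is essentially arbitrary — control risks were observed to
  flip from ~0 to ~1 under zero occlusion, drowning the maps in artifacts —
  while mean-filled volumes stay in-distribution and the maps localize
  cleanly.
- *Matched pairs* use all available true positives (capped at 124). Because
  cases report systematically more pain, candidate controls are first
  caliper-restricted per stratum to KOOS within ±15 points of the
  stratum's case mean — a standard matched-design device; the random
  accept/reject matcher with its paired t-test then runs on that pool.
  Cases per stratum are capped at half the calipered pool (matching is
  without replacement; a pool-sized case set forces every control into the
  sample and the acceptance test has no freedom), and if the matcher
  exhausts its attempts the case farthest in KOOS from its stratum's pool
  is dropped and matching retried.
- *Degenerate strata.* If a validation stratum lacks one class, its
  ensemble is selected by AUC on the full validation set instead —
  a documented fallback for small cohorts.

The study asserts: both planted tissues significant with OR > 1, and at
least 7 of the 8 noise tissues non-significant. Occasionally one noise
tissue reaches significance with OR < 1 — case hotspot budgets are spent on
the planted tissues, depleting high-intensity bystander tissues relative
to controls — which mirrors the depletion phenomenology such analyses show
on real data and is why the criterion tolerates a single noise-tissue hit.

## Known limitations

- The NumPy network trains desk-scale models only; the full-scale
  configuration is constructible and runs forward, but training it is out
  of practical reach without accelerator support.
- Batch-norm statistics make single-volume inference depend on running
  averages; all evaluation therefore uses inference mode.
- kNN imputation and feature screening operate cohort-wide (imputation
  preceding the split, as in the source design); a strictly split-safe
  variant would fit imputation on the training split only.
- The generator's clinical-variable distributions are stand-ins; effect
  sizes for anything but KOOS pain, age and BMI are invented.
- Visit-level TKR times are drawn independently per visit; within-patient
  consistency of event times (and contralateral replacements) is not
  modeled.
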
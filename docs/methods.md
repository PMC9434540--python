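# Methods

## Problem and models

Two radiographs of one patient share stable anatomy — lung outline, rib
cage, heart shadow, clavicles, diaphragm contour — under heavy acquisition
nuisance (windowing, pose, scale, follow-up intervals, disease change).
`cxreid` audits how much identity that anatomy leaks, with two siamese
convolutional networks that share one backbone parameter store across both
branches (weight sharing is a contract: there is a single parameter set,
never a copy).

**Verification.** Each branch maps a prepared input (resized to S×S,
scaled to [0,1], replicated to 3 channels, standardized with the
natural-image-pretraining channel statistics) to a 128-d code z. The merge
is ŷ = σ(FC(|σ(z₁) − σ(z₂)|)) with a single 128→1 FC layer, so the score is
exactly symmetric in its inputs. Training: binary cross-entropy, Adam on
mini-batches of 32 pairs, early stopping on validation AUC with patience 5,
best-validation weights restored. Pairs are mined offline: all C(n,2)
same-patient combinations are positives; negatives are distinct random
cross-patient pairs, drawn once (FTS) or redrawn each epoch from
hash(seed, epoch) (RNP). Epoch sets are balanced (N_s/2 positives, N_s/2
negatives).

**Retrieval.** The backbone's feature volume is pooled twice adaptively
(average and max, each to C×5×5), concatenated to 2C maps, reduced by a 1×1
convolution to 100 maps, flattened (2500) and passed through FC 2500→512→128.
Adaptive pooling makes the head independent of input resolution, so one
trained network evaluates at any side ≥ the backbone stride. A gallery query
ranks all other images by Euclidean embedding distance (ties broken by image
id); metrics are mAP@R, R-Precision and Precision@1 over queries with at
least one relevant gallery item (single-image patients are excluded from the
query set and counted). AP@R sums P@i·rel@i over ranks 1..R; the alternative
reading — over the ranks of the first R relevant items — is available behind
a flag.

On the 2048-vs-4096 question for the 1×1 convolution input: concatenating
the two pooling outputs doubles the backbone width, so the convolution maps
2C → 100 (4096 → 100 for a 2048-channel backbone); the quoted "2048" is
read as the per-branch width.

## Training schedule details

Retrieval training runs two phases: the head alone for `epochs_head` with
the backbone frozen, then everything for `epochs_full`, each under its own
1cycle schedule (cosine rise to the peak at 30 % of the cycle, cosine fall
back; the learning rate changes after every batch). The full-scale preset
keeps the published bounds 0.0063 → 0.1584 (chosen by an LR range test),
weight decay 1e-5, batch 32, margin m = 1, cross-batch memory 128
(= last 4 batches), 30 + 50 epochs. An LR range test
(`training.lr_range_test`: exponential sweep, suggestion at the steepest
smoothed-loss descent) is included for re-deriving bounds on new backbones.

Batches are assembled patient-by-patient (a shuffled patient order, all of a
patient's images appended until the batch is full) so every batch contains
positive pairs; all C(b,2) within-batch pairs plus batch×memory pairs enter
the loss.

## Desk-scale preset (`desk_scale_config`)

The full-scale configuration (50-layer pretrained residual backbone,
1024 px inputs, 10⁵-image cohorts) needs GPUs and external data. The desk
preset is the configuration every test runs: tiny 3-block CNN backbone
(48 base channels, stride 8, ~0.4 M parameters), 64 px inputs, 200-patient
phantom cohorts, verification epochs ≤ 25 (early stopping typically fires
near epoch 20), retrieval 3 + 5 epochs. Three deliberate deviations from the
full-scale recipe, each forced by the small regime and visible in ablations:

* **Cross-batch memory off.** XBM rests on "slow drift": embeddings change
  little between consecutive iterations, so recent snapshots are valid
  negatives. With ~16 batches per epoch and a fresh network under 1cycle
  rates, drift is fast; stale entries act as random repulsion and measurably
  destroy the metric (held-out Precision@1 0.51 with memory vs 0.97 without,
  same seed). The memory itself (FIFO, detached snapshots, capacity 128
  default) is fully implemented and tested.
* **Balanced loss reduction.** Online mining yields ~1 % positive pairs. A
  plain mean over pair losses lets the positive term vanish into the
  negative mass; the desk default averages positive and negative pair losses
  separately and sums the two means. The per-pair loss is unchanged.
* **Unit-normalized embeddings.** The desk retrieval model L2-normalizes its
  output, bounding pair distances by 2 so margin 1 stays active and float32
  SGD remains stable. Evaluation uses plain Euclidean distance on the
  model's output either way; un-normalized embeddings remain the default for
  the model class.

The desk 1cycle bounds (0.005 → 0.05 retrieval SGD; Adam 1e-3 for
verification) were fixed once for the tiny backbone.

## Phantom cohort generator

Each patient is a geometric latent sampled from documented uniform ranges:
body-silhouette width, per-lung ellipse semi-axes and position, rib count
and curvature, heart ellipse size/offset, clavicle angle, diaphragm
amplitude. Each image re-renders that latent under per-image nuisance:
window center/width, rotation (±4°), scale (±5 %), translation (±3 %),
additive Gaussian noise (sd 0.02 of full scale), AP/PA flip (10 %, rendered
as a mirror plus an enlarged heart shadow), aging drift per follow-up year
(global rescale +0.6 %/y, diaphragm rise), and disease marks — bright
Gaussian blobs tied to finding labels, persistent across a patient's
follow-ups, with new findings appearing at follow-up with probability 0.15.
Counts mirror the reference archive's structure: images per patient
1 + Poisson(2.5) (mean 3.5), ages 20–80, follow-up gaps Poisson(1.2) years.
All randomness flows from one seed through three named substreams
(identity, nuisance, labels); a fixed config reproduces every byte.

`NuisanceRanges.scaled(level)` multiplies the stochastic ranges only, which
gives the monotone-degradation harness its x-axis. The parameter-recovery
condition uses level 0.5 ("low nuisance"); degradation checks use levels
0.5 / 2 / 4; the aging-drift analysis boosts the drift coefficients and
suppresses other nuisance so the age-gap effect is identifiable.

What the phantom does **not** emulate: radiographic physics, anatomy beyond
schematic geometry, scanner- or site-specific noise signatures, foreign
material (pacemakers, clips), and non-rigid deformation between follow-ups.
Passing parameter recovery on phantoms therefore demonstrates that the
implementation learns and retrieves identity from geometry under nuisance —
it does not quantify performance on real radiographs.

## Evaluation choices

* AUC is the two-sample rank statistic with midrank tie correction
  (identical to the ROC integral); the bootstrap CI is the percentile
  interval over resampled scored pairs (replicates with one class redrawn).
  Pairs sharing an image are resampled as if independent — a caveat of
  evaluating on pre-built pair sets.
* Threshold ties (score = t) count positive.
* Confusion statistics with zero denominators are reported as missing, not
  raised. Table output rounds half-up to 4 decimals.
* Subgroup TPR analyses use positive pairs only: age gap binned on supplied
  integer-year edges (pairs beyond the last edge are omitted), disease
  change contributes a pair to the bin of every finding newly appearing in
  the later image, view change compares AP/PA flags; records with unknown
  attributes are excluded.
* Grad-CAM targets the pre-sigmoid pair logit; channel weights are the
  spatial means of the gradient at the chosen post-ReLU conv layer, and maps
  are rectified. Swapping the input pair swaps the maps exactly.

## Numerical notes

* The autograd engine (`cxreid.nn`) is float32 for parameters/activations
  with float64 losses where inputs are float64; gradients were verified
  against central differences at 1e-6 relative tolerance.
* The contrastive distance uses d = √max(d², 1e-12); a negative pair at
  exactly zero distance has zero subgradient.
* BCE clamps scores to [1e-12, 1 − 1e-12].
* `one_cycle_lr` hits the lower bound exactly at step 0 and the upper bound
  exactly at the peak step.
* Degenerate inputs (empty galleries, single-class score sets, single-image
  batches) raise argument errors rather than returning conventions.

## Problem sizes used by the test and acceptance runs

Parameter recovery: 200 patients (~690 images), 64 px, verification
N_s = 2·min(positives, 700) ≈ 1400 pairs/epoch, retrieval 3 + 5 epochs.
Degradation: three 60-patient cohorts at nuisance levels 0.5/2/4; aging
drift: one 120-patient cohort. Metric-oracle equivalence: hundreds of
randomized galleries/score sets of ≤ 12 items against exhaustive
enumeration at 1e-12.

## Known limitations

* The desk backbone is not pretrained; conclusions about pretrained
  full-scale backbones do not transfer automatically.
* XBM is validated mechanically (FIFO, capacity, detachment) but its
  training benefit only manifests at scales this package does not run.
* The bootstrap treats pairs as exchangeable units.
* The phantom's identity signal is stronger and cleaner than real thorax
  biometrics; absolute metric values on phantoms are not comparable to
  values on radiograph archives.
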
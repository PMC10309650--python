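# Methods

## Problem setting

Given numeric descriptor tables for `n_d` drugs and `n_t` targets and a
set of known interacting pairs, the task is binary classification over
drug–target pairs, with three evaluation regimes: held-out pairs (both
entities seen in training), held-out drugs, and held-out targets (the
cold-start regimes).  Known interactions are the only positives;
negatives are sampled from the unobserved cells of the interaction
grid, which makes them *presumed* negatives — a standard, imperfect
convention in this field.

## Preprocessing

Descriptor columns differ in scale by orders of magnitude, so each
table is standardised (centre, unit variance; zero-variance columns get
scale 1 with a warning) before PCA.  Each entity type has its own PCA
with default dimension `d = 100`; a pair vector is the drug block
concatenated with the target block.  Two choices here are genuinely
open and worth stating:

* **Per-fold fitting (default `pca.per_fold: true`).**  PCA is refit on
  the entities that appear in each fold's training pairs and applied to
  the held-out entities.  Fitting once on all entities would leak
  held-out-entity information into the representation under the
  cold-start schemes.  The global variant remains available for
  sensitivity analysis.
* **Dimension capping.**  A table with fewer rows or columns than `d`
  cannot support `d` components; the pipeline caps `d` at
  `min(n_entities, n_features)` per table and logs the cap.  `fit_pca`
  itself treats an inadmissible `d` as a hard error.

Component signs are canonicalised (largest-magnitude loading positive)
so runs are bit-reproducible.

## Base learners

**Boosted shallow networks.**  Raw-score additive model
`F(x) = F0 + Σ α_k f_k(x)` with `F0` the prior log-odds and each `f_k`
a 2×16-unit rectifier MLP with linear output.  Stages fit the Newton
residuals of the logistic loss (`targets −g/h`, weights `h`,
`h` floored at 1e-12 to avoid division blow-up near saturation), one
epoch of Adam per stage (lr 0.05, batch 64, L2 0.001 on weights only),
constant step size `α_k = 1.0`.  Two guards make training monotone: a
stage whose weighted objective is worse than the zero function is
zeroed out, and the corrective step (one joint Adam epoch over all
learners against the additive-score cross-entropy) restores pre-step
parameters if the full-data training loss rises by more than 1e-6.
Inputs to every learner are the raw pair features; no hidden-state
propagation between learners.  The hidden architecture is a documented
default, configurable — nothing in the method fixes it.

**Feed-forward network.**  [256, 64] rectifier stack, single sigmoid
unit, Adam at lr 1e-3, exactly 100 epochs of shuffled size-64
mini-batches, no early stopping or dropout.  Probabilities are clipped
to [1e-12, 1−1e-12] before logs.  Both neural components run on a
small NumPy MLP core (He initialisation, log-domain stable loss
evaluation); determinism comes from seeding the initialisation and the
batch shuffles.

**Cascade deep forest.**  Layers of ten tree ensembles: five random
forests (bootstrap, `sqrt` feature subsampling) and five extra-trees
forests (random cut-points, `sqrt` subsampling, no bootstrap),
unlimited depth.  An earlier variant using single-random-feature extra
trees measured consistently worse on the planted worlds at equal cost,
so the Geurts classification default is used.  Each layer's ten
two-class probability outputs form a 20-dimensional class vector; layer
`ℓ > 0` consumes `[base features ‖ previous class vector]`.  The class
vectors used during growth are cross-fitted over 3 stratified folds —
feeding a layer its own predictors' training fit would let the cascade
bootstrap on memorised labels.  Growth stops when the cross-fitted
committee accuracy fails to beat the best seen by more than 1e-4, or at
20 layers; prediction uses the best-scoring layer's committee (the last
layer is a config option), with every predictor refit on all rows.

## Fusion and decision rule

Weights are constrained to the unit simplex so the fused score stays a
probability and the fixed threshold keeps its meaning; the candidate
set is the simplex lattice with step 0.1 (66 triples), scored by AUPR
on a tuning slice (20% of training pairs; whole entities under the
cold-start schemes so the slice is entity-disjoint), ties broken by
AUC, then largest α, then β.  Because the vertices are in the grid, the
tuned vote can never lose to a single learner on the tuning slice —
this is asserted on every training run.  By default the component
models trained on the 80% remainder are kept as-is: the tuned weights
describe *those* models, and refitting on all training pairs (available
as `ensemble.refit: true`) changes the components the weights were
selected for while doubling cost.  Classification is strict:
positive iff score > 0.5.

## Negative sampling and cross-validation

Negatives are drawn uniformly without replacement from unknown cells at
`round(ratio · n_positives)` (ratio 1 by default), once per repetition
*before* fold construction so every fold sees a consistent balanced
set.  Entities (or pairs) are shuffled and dealt into 5 folds,
remainders to low-index folds; under the entity schemes a pair sits in
the fold of its held-out entity.  Repetition `r` uses seed
`base_seed + r`; both the negative sample and the folds are redrawn per
repetition (each independently switchable).  Fold predictions are
pooled within a repetition before metrics are computed — less biased
than averaging per-fold metrics when entity folds are small — and
headline values are means over repetitions.

## Metrics

Precision, recall, accuracy and F1 come from the confusion table at
the strict 0.5 rule, with precision := 0 when nothing is predicted
positive and F1 := 0 when precision + recall = 0.  AUC is the
tie-aware Mann–Whitney rank statistic (exact, O(n log n)); AUPR is the
average-precision form of the PR step curve.  Tests verify both
against brute-force pairwise counting and exhaustive threshold
enumeration.

## Synthetic worlds

The generator plants a logistic low-rank ground truth: latent factors
`u_i, v_j ~ N(0, I_r)`, features as noisy linear images of the
factors, and `P(interaction) = σ(s·u_i·v_j + b)` with labels drawn
from that probability and flipped with probability ε.  Defaults:
300 drugs × 30 targets, rank 4, feature dims 300/500 (scaled-down
stand-ins for the ~1.5k/10k descriptor tables real extractors
produce), feature noise 0.1, ε = 0.05, steepness `s = 6`, intercept
`b = −8` (≈26% prevalence).

The steepness parameter deserves a note: with `s = 1`, Bernoulli
sampling alone caps the achievable AUC near 0.77 regardless of method
— the world would mostly measure irreducible label noise.  `s = 6` is
the smallest integer scale at which ranking by the true latent logit
reaches AUC ≥ 0.95 on an easy noiseless world, so learner scores
reflect recoverable structure; the intrinsic ceiling of the default
world (measured by the true-logit oracle on a balanced sample) is
about 0.91.  What the planted world does *not* emulate: binary/sparse
fingerprint blocks, descriptor collinearity structure, hubness and
degree skew of real interaction networks, and biased (non-uniform)
missingness of negatives.  Passing tests therefore demonstrate correct
mechanics and recoverability of low-rank signal, not benchmark-level
performance on curated data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
default 300×30 world with forests reduced to 25 trees and single
repetitions per seed — a deliberate desk-scale configuration; the
full settings (100 trees, 20 repetitions) are the config defaults and
are what `scripts/reproduce_benchmark.py` uses on user data.  Floors
and tolerances: `h ≥ 1e-12` in boosting targets, probability clipping
1e-12 in cross-entropy, corrective-step guard 1e-6, cascade stopping
tolerance 1e-4, simplex-sum check 1e-9.  Ranking ties break by
(drug_id, target_id) lexicographic order so score reports are
byte-identical across runs.

## Known limitations

* Presumed negatives: sampled "negatives" may be undiscovered
  positives; AUPR in particular is pessimistically biased.
* The boosted-net and feed-forward architectures are defaults, not
  tuned; on real descriptor tables wider stacks may pay off.
* The cascade is the weakest committee member on low-rank planted
  worlds (axis-aligned splits capture multiplicative latent
  interactions poorly); the soft vote compensates by down-weighting
  it.
* No probability calibration is applied before voting; component
  scores are averaged as-is.
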
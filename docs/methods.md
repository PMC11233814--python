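# Methods

This note documents the model, the numerical and design choices the package
makes where the procedure is genuinely open, what the synthetic data does and
does not emulate, and the known limitations.

## Model and training procedure

The regression framework has two phases operating on standardized features.

*Phase 1 — contrastive representation learning.* Each mini-batch `X` (size
≤ 2048) is augmented with a corrupted copy `X̃` (corruption rate c = 0.5:
per sample, `round(c·d)` feature positions chosen uniformly without
replacement are overwritten with the value another uniformly chosen row of
the batch holds at that position; labels are kept). Both halves pass through
the encoder `Enc` (4 affine layers, width 256, ReLU after each) and the
projector `Proj` (256→256→256, ReLU between, none after the last), are
L2-normalized, and scored with the supervised contrastive loss. Positives
are all pairs with |Δy| < θ (strict inequality; θ = 0.35 for labels with
unit SD), so an original and its corrupted twin (Δy = 0) are always
positive. The loss is summed over anchors as the defining formula states; an
anchor with no positives contributes 0 (possible only without augmentation).
Optimization is Adam at learning rate 0.001.

*Phase 2 — fine-tuning.* The encoder is frozen (asserted bit-identical
before/after), the projector is discarded, and a regression head `Reg`
(256→256→1, ReLU between) is fit with MSE loss, batch 128, a fresh Adam
optimizer. Because the encoder is frozen its outputs are computed once and
cached; this is exact, not an approximation.

An MLP baseline — the same Enc+Reg stack trained end-to-end with MSE — is
included as the reference model.

### Early stopping and the pretraining monitor

Both phases stop when the validation signal fails to improve for 3
consecutive epochs, returning the best-epoch parameters (the conservative
reading of early stopping; "last epoch" is not used). Fine-tuning monitors
validation MSE.

Which quantity the *contrastive* phase should monitor is an open design
point. The package defaults to a **linear-probe monitor**: each epoch, a
closed-form ridge readout (shrinkage 0.03·n_train on the 256-dimensional
embeddings) is fit on the frozen training embeddings and its validation MSE
is the early-stopping signal. The alternative, monitoring the validation
contrastive loss itself (`pretrain_monitor="contrastive"`), is retained but
is a poor proxy for downstream regression quality: on high-dimensional
uncorrelated inputs the contrastive objective begins memorizing the training
batch almost immediately, its validation value deteriorates from the first
epochs, and stopping on it returns a near-initialization encoder — while a
probe shows the representation still improving for several epochs. The probe
measures exactly what phase 2 will consume, which is why it is the default.

### Initialization

Layers are initialized uniformly on ±1/√fan_in (weights and biases), the
de-facto default for affine layers in the major deep-learning frameworks.
The scale matters more than the distribution here: variance-preserving
(He-style) initialization of a wide 6-affine-layer stack on ~1000
uncorrelated standardized inputs memorizes the training set before any
generalizable structure forms, costing roughly 0.25 in held-out r on the
synthetic benchmark; the smaller uniform initialization trains in a regime
where early stopping can find a generalizing epoch. Initialization is fully
seeded; training is deterministic end to end given the seed.

### Other numerical choices

- Features are z-scored per column with statistics from training rows only
  (FA ~0–1, MD ~1e-3 mm²/s, and NoS counts are on incompatible scales);
  zero-variance columns get scale 1, mapping to exactly 0. Labels are used
  as-is (component scores already ~[−3, 3]). Zero-filled empty-cluster
  entries are standardized like any other value.
- The contrastive loss is stabilized by subtracting the per-anchor maximum
  logit (analytically a no-op). Its gradient is analytic:
  dL/dZ = (G + Gᵀ)Z/τ with G the softmax-minus-positives matrix.
- Training mathematics run in float32; the loss value itself is accumulated
  in float64. Parameters serialize losslessly (binary archive + JSON
  manifest) and reload bit-identically.
- Split sizes floor the validation and test fractions and give the remainder
  to train. Batches that collapse below 2 samples are skipped (corruption
  needs a donor row).
- |Δy| exactly equal to θ is a negative pair (strict inequality).
- Degenerate statistics raise: Pearson r of a constant vector, paired t-test
  of zero-variance nonzero differences. A permuted prediction that comes out
  constant during importance scoring is treated as accuracy 0 rather than an
  error.

## Feature importance

Grouped permutation importance scores feature j as the mean of
(baseline r − permuted r) over all permutations whose group contained j;
inclusion counts are tracked and must sum to group_size × n_permutations.
Groups are drawn uniformly without replacement; each selected column is
shuffled with an *independent* row permutation (a shared permutation would
preserve within-group covariance). Negative decreases are kept, not clipped.
Ties in the final ranking break deterministically by feature id.

Two modes: `retrain` (shuffle training rows, retrain, evaluate the clean
test set — the literal protocol, one retraining per permutation, intended
for small runs) and `test_permute` (shuffle test rows of one fixed model —
the scalable surrogate, which reduces to classical single-feature
permutation importance at group_size 1). At the full published scale (50,000
permutations × 10 splits) `retrain` implies half a million trainings;
`test_permute` exists because of that cost, and the two modes answer
slightly different questions (what the *pipeline* depends on vs what the
*fitted model* depends on).

## Evaluation protocol

Pearson's r on the held-out test set, repeated over independent 70/10/20
splits (10 in the full protocol; configurable) with every compared method
receiving identical splits. Methods are compared by two-sided paired
t-tests on the per-split r values; a one-way within-subject ANOVA (no
sphericity correction, via statsmodels AnovaRM) is provided as the omnibus
companion. No multiple-comparison correction is applied by default.

## Synthetic data

The generator emulates the tabular form of a tractometry study: per measure
an n×d matrix (d = 953 by default), i.i.d. standard-normal latent features
mapped affinely onto measure-typical scales (FA ≈ 0.5±0.1, MD ≈
7.8e-4±8e-5 mm²/s, NoS ≈ 300±120), a label
y = Σ w·x + ε rescaled to unit sample SD, and zero-inflation applied after
the label is built (so zeros corrupt the observed features the way empty
clusters do — note a raw 0 is ~5 SD off-scale after standardization, which
is why the default rate is a modest 0.02). Effect weights are fixed-magnitude
random-sign (±1): every planted feature carries the same effect, making
"informative" a well-defined, recoverable property; the noise ceiling is
then exactly r_max = sqrt(k/(k+σ²)) and σ can be solved for a target
ceiling. The informative set is split round-robin across measures so
ensembling has complementary information to exploit. An optional `nonlinear`
variant applies tanh to the signal (ceiling then estimated from the sample).

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: inter-cluster covariance (real
microstructure features are strongly correlated; synthetic ones are
independent), site effects, non-Gaussian measure distributions, and
structured missingness. The independence assumption is consequential: with
~1000 uncorrelated inputs and a few thousand subjects, deep networks of this
architecture reach roughly 0.39–0.45 test r against a 0.6 ceiling where a
sparsity-aware linear model (lasso) reaches ~0.56, and the contrastive
pipeline trails the plain MLP baseline by a few hundredths — corruption
augmentation replaces feature values that, with independent features, cannot
be recovered from the remaining ones, so part of the per-view signal is
simply deleted. On correlated real data corrupted features are largely
redundant with their neighbours, which is the regime the method was designed
for. Recovery tests on synthetic data should be read as calibrations of the
pipeline mechanics, not as bounds on real-data performance.

## Problem sizes used in the shipped studies

The test-suite and reproduction-script studies use n = 4000 subjects at
d = 953 features (full-width recovery), n = 2500 at d = 150 (three-measure
ensemble study), n = 2000 at d = 50 (noise-free sanity task), and n = 1000
at d = 100 with 2000 permutations (importance recovery); these sizes give
stable estimates while keeping a full run in the minutes range on one CPU.

## Known limitations

- Single-threaded NumPy training: fine at the shipped scales, not intended
  for datasets orders of magnitude larger.
- The probe monitor uses labels during representation learning's model
  selection; this is consistent with the supervised setting but means the
  pretraining phase is not label-free.
- The repeated-measures ANOVA applies no sphericity correction and the
  paired t-tests no multiplicity correction (a Bonferroni adjustment is a
  one-line multiplication for users who want it).
- `retrain`-mode importance at published scale is computationally
  impractical; `test_permute` is the supported large-scale mode and is
  clearly labelled a surrogate.
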
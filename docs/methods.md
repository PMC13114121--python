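# Methods

## Problem and model

`priorvae` predicts a binary clinical phenotype — response to immune
checkpoint inhibition — from gene-level gut-microbiome abundance.  Each
sample is a vector of RPKM values (reads per kilobase of contig per million
mapped reads) over a fixed reference set of assembled contigs, so features
measure microbial gene content rather than taxonomic composition.  The core
model is a supervised variational autoencoder whose latent space is
conditioned, through multi-head attention, on a fixed matrix of
protein-sequence embeddings ("biological prior knowledge"):

* **Encoder.**  x ∈ R^M → 512 (linear, batch norm, ReLU) → d = 256, giving
  the latent mean μ.  The activation after the first encoder layer is a
  design choice of this package; a purely affine encoder would collapse the
  two layers into one.
* **Reparameterization.**  z = μ + ε, ε ~ N(0, I) during training; ε = 0 in
  evaluation mode, which makes all inference deterministic.  The posterior
  variance is fixed at one, so the KL term reduces to ½‖μ‖².
* **Prior attention.**  The prior matrix R ∈ R^{P×320} is projected by a
  trainable linear map to R′ ∈ R^{P×d}; R itself receives no gradient.
  Scaled dot-product attention with query μ and keys/values R′, H = 4 heads
  of width d/H, output mixing W_o and layer normalization produce the
  prior-aware embedding a ∈ R^{B×d}.  H is a free parameter (the head count
  is not pinned down by the model definition); d must be divisible by H.
* **Fusion and decoder.**  z̃ = λz + (1 − λ)a with λ = 0.7; the decoder maps
  z̃ (width d = 256) → 512 (batch norm, ReLU) → M (batch norm) with a final
  sigmoid.  Defining z̃ at width 256 and letting the decoder's first layer
  expand to 512 is the only shape-consistent reading of the architecture:
  a convex combination requires both operands at width d.
* **Classifier.**  μ → 128 → 64 → 1 (batch norm + ReLU per hidden layer,
  sigmoid output).  The classifier reads μ, not z, so predictions carry no
  sampling noise.

**Loss.**  L_total = λ_rec·L_rec + λ_KL·L_KL + L_cls with λ_rec = 0.1,
λ_KL = 0.2.  L_rec is the squared reconstruction residual per sample,
averaged over the batch.  L_KL and L_cls are batch means by default so that
loss magnitudes are batch-size invariant; `loss_reduction="sum"` restores
literal per-batch sums.  The decoder's sigmoid bounds reconstructions to
(0, 1) while targets are z-scored and unbounded; the default keeps the MSE
against z-scored targets as defined, and
`reconstruction_target="minmax"` instead rescales targets per feature into
[0, 1] for a range-consistent variant.  With λ_rec = λ_KL = 0 and λ = 1 the
model reduces to an MLP classifier on μ, which is the ablation sanity floor
exercised in the tests.

**Numerics.**  The network runs on the package's own reverse-mode autodiff
core (`priorvae.nn`): float64 numpy throughout, gradient-checked against
central finite differences in the test suite.  Weights use fan-in uniform
initialization U(±1/√fan_in) from a seeded generator; batch-norm running
statistics use momentum 0.1 with the unbiased variance estimate; training
batches of size 1 are dropped (batch statistics are undefined) and logged.
Adam (β = 0.9/0.999, ε = 1e−8) with learning rate 1e−3, batch size 8, and a
fixed epoch count (default 500; no early stopping, no schedule).  All
randomness — fold splitting, initialization, reparameterization noise,
batch order — derives from integer seeds (default 42), so full runs are
bit-reproducible.

## Pipeline conventions

**Standardization.**  Features are z-scored with the population-SD
convention (divide by n; `convention="sample"` available).  Zero-variance
features map to exactly 0 rather than being dropped, preserving the input
dimension across folds and cohorts.  Scalers are fitted on the training
fold only and applied to validation/test data; a global scope is available
but leaks validation statistics into training and is not the default.

**Feature screening.**  Features are ranked by mutual information with the
label and the top k retained (k = 80,000 at full scale; small k for
synthetic runs).  The default estimator is a plug-in estimate on ≤ 8
quantile bins per feature: RPKM columns carry a large atom at exactly zero,
and the quantile binning absorbs it deterministically, whereas the
k-nearest-neighbour estimator's tie-breaking jitter dilutes weak signal in
such columns (measured: at a 1-SD planted effect, n = 200, the binned
estimator places ≥ 80% of planted features in the top 2×|planted|, the
neighbour estimator does not).  The neighbour estimator (k = 3, seeded)
remains available via `estimator="knn"`.  Selection runs inside each
training fold by default; a global scope reproduces study-level selection.

**Evaluation.**  Stratified five-fold cross-validation (seed 42 covers the
split and the model init).  Accuracy at threshold 0.5; AUC by trapezoidal
integration of the ROC curve; AUPR by step-wise precision–recall
integration (no interpolation) — both via scikit-learn, whose conventions
match.  Confidence intervals are percentile bootstrap (2.5/97.5) over
sample-level resampling; replicates that resample a single class are
skipped.  AUC differences between two scorers on the same samples are
tested with a two-sided paired bootstrap of ΔAUC (2000 replicates); this is
a pragmatic choice where no canonical test is mandated.  The LASSO baseline
is L1-penalized logistic regression with the penalty chosen by inner CV,
on the identical fold assignment.

**Cross-cohort transfer.**  One model per training cohort, trained on all
its samples after alignment onto a fixed reference feature list (missing
features zero-filled, extra features dropped); every test cohort is aligned
identically and standardized with the training cohort's scaler.  AUC is
reported as a test × train matrix.

**Attribution.**  Integrated gradients on the responder-probability output
F: attr_j = (x_j − x0_j) · mean over a midpoint grid of ∂F/∂x_j along the
straight path from the baseline x0.  Baseline is the all-zero vector in
standardized space — the per-feature training mean on the raw scale — and
50 path steps by default (completeness checks use ≥ 200).  The completeness
identity Σ attr = F(x) − F(x0) holds to well under 1% at 200 steps for
samples with a non-negligible output difference; the relative error
necessarily grows as F(x) − F(x0) → 0, so tests gate the 200-step relative
check on |ΔF| ≥ 0.1 and verify convergence at 1000 steps otherwise.
Attributions are averaged over correctly predicted (threshold 0.5)
validation samples pooled across folds, separately for predicted responders
and predicted non-responders; both groups attribute the same
responder-probability output, so non-responder tables naturally mix signs.
Cumulative genus/family scores are sums of member-feature means, which
conserves total attribution exactly.

## Reference sets and RPKM

Contigs shorter than 500 bp are removed (the boundary keeps exactly 500).
Within each genome bin contigs are ranked by length descending, ties broken
by contig id ascending (a deterministic choice this package makes; nothing
upstream fixes it), and the top k kept — k = 1 for the protein-prior
reference, k = 200 for the abundance reference, all contigs when a bin has
fewer.  RPKM_i = count_i / ((length_i/10³)·(total_mapped/10⁶)); mapping
itself is out of scope and counts are consumed as tables.

## Synthetic cohorts

The generator emulates the statistical shape of real RPKM tables, not their
biology: non-zero entries are log-normal (exp of a standard normal), each
entry is zeroed with probability π₀ = 0.6 (zero inflation), a planted
subset of k_inf features has its log-mean shifted by +δ (in within-class SD
units) in responders, and per-cohort distribution shift multiplies each
feature by a log-normal factor with log-SD equal to the shift scale.
Responder fraction defaults to 0.4, mirroring the roughly one-third
responder share typical of checkpoint-inhibitor cohorts.  The prior matrix
is standard normal and carries no label signal by default, so the model
must learn to use or ignore it.  What the generator does *not* emulate:
phylogenetic correlation between features, compositionality, batch effects
beyond a per-feature multiplicative shift, and genuine protein-embedding
geometry — so passing tests demonstrate that the machinery recovers planted
multiplicative signal under sparsity and shift, not that it will attain any
particular performance on real cohorts.

## Problem sizes used in tests and the acceptance script

Synthetic evaluation runs the study conditions n = 200, M = 500,
k_inf = 20, δ = 2, π₀ = 0.6, seed 42, with MI selection to k = 40 inside
each fold and training reduced to 100 epochs (the loss plateaus well before
that at these sizes; the 500-epoch default is kept for full-scale use).
Cross-cohort checks use two cohorts with shift scale 0.3.  Bootstrap
coverage is assessed over 200 simulated binormal datasets with 1000
replicates per interval; bootstrap AUC replicates are computed with the
midrank (Mann–Whitney) identity, which equals trapezoidal ROC integration
exactly and vectorizes over replicates.  The determinism check repeats a reduced run
(n = 60, M = 60, 20 epochs) end to end and requires bit-identical folds,
metrics and attributions.

## Known limitations

* The sigmoid-decoder / z-scored-target mismatch biases reconstructions
  toward (0, 1); classification dominates the composite loss (λ_rec = 0.1),
  so this mainly affects the reconstruction diagnostics.
* The KL term regularizes only the latent mean (unit variance is assumed,
  not learned); the model is a regularized supervised embedding rather than
  a full generative VAE, and no generative sampling API is provided.
* Pure-numpy training is practical at the synthetic scales above but not
  for M ≈ 10⁵ features at 500 epochs; the architecture is size-agnostic,
  the compute budget is not.
* The paired-bootstrap AUC test and the MI estimator are explicit package
  choices; results need not match analyses that used other conventions.
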
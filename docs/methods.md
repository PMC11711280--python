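# Methods

## The problem

Multivariate recordings of human brain activity — e.g. single-subject fMRI
multivoxel patterns — are feature-rich but exemplar-poor: a ventral temporal
cortex region of interest may have ~2,400 voxels but only a few thousand
trials, of which much of the variance is structured noise unrelated to the
subject's task. Unsupervised dimensionality reduction (PCA, autoencoders)
compresses whatever dominates the variance, which in this regime is often
precisely the task-*irrelevant* structure. `tracebench` implements a
task-relevant autoencoder — TRACE — that biases the compression toward
behaviorally relevant directions, plus the complete evaluation harness needed
to compare it fairly against unsupervised baselines.

## Model

TRACE is a fully-connected autoencoder with one tanh hidden layer on each of
the encoding and decoding arms, a linear bottleneck of width `d`, and a
multinomial logistic (softmax) classifier head attached to the bottleneck.
With input `X` (m trials × n features), reconstruction `X̂`, one-hot labels
`y` over `k` classes and head probabilities `ŷ`, the training objective is

    L = L_R + α·L_CE
    L_R  = (1/(m·n)) Σ_ij (X̂_ij − X_ij)²
    L_CE = −(1/m) Σ_i Σ_c y_ci log ŷ_ci

`α ≥ 0` weights the classifier term. At `α = 0` the objective — and, under a
shared seed, the entire training trajectory — is exactly the standard
autoencoder (AE), which is the complexity-matched baseline. The other
baselines are a diagonal-Gaussian VAE with the same layer sizes (encoded at
evaluation time by its posterior mean) and PCA on the top `d` components.

The networks are implemented directly in NumPy with manual backpropagation
and Adam, which keeps every fit bit-reproducible under a fixed seed; PCA and
the post-hoc logistic probes use scikit-learn.

### Architectural and numerical choices

* **Hidden activation** tanh; **bottleneck** linear (the VAE posterior mean
  must be unconstrained, and keeping the bottleneck linear for all families
  keeps the comparison matched). **Reconstruction output** is linear for
  data on an arbitrary scale (z-scored tabular) and logistic for data in
  [0, 1] (images); `output_activation="auto"` chooses by the training-data
  range.
* **Hidden width** defaults to 512 for 784-dimensional inputs and
  `min(n, 1024)` otherwise, identical across TRACE/AE/VAE.
* **Optimizer** Adam, learning rate 1e-3, batch size 128, up to 100 epochs
  with loss-plateau early stopping (patience 10, min_delta 1e-6). All
  overridable; these are standard, stable defaults for networks of this
  size.
* **α default 1.0** — reconstruction and classification on equal footing.
* **Probability clipping** at 1e-12 inside logs: the cross-entropy is never
  infinite.
* **VAE KL term** is normalized per element, `L = MSE + (1/(m·n)) Σ_i KL_i`,
  so the two terms share a scale regardless of `n`; log-variances are clipped
  to ±15 for numerical stability.
* **Initialization** symmetric uniform with fan-in scaling, drawn in a fixed
  order (encoder, decoder, classifier head, VAE log-variance head) so that
  families sharing a seed share their encoder/decoder starting point. Batch
  shuffling and VAE reparameterization noise use separate child streams of
  the run seed.
* **Divergence** (non-finite loss) raises an error naming the epoch rather
  than silently producing NaN metrics.

## Outcome metrics

All metrics are computed on a held-out test split.

1. **Reconstruction fidelity** — mean per-trial Pearson r between each test
   input and its reconstruction. Zero-variance trials are excluded with a
   warning.
2. **Bottleneck classifier accuracy** — top-1 accuracy of an L2-regularized
   multinomial logistic regression trained *after and independently of* the
   main model on training-split bottleneck activations. The regularization
   weight λ is a fixed constant (1.0), identical for every model and space,
   so differences reflect representations rather than probe tuning
   (scikit-learn's `C = 1/λ`).
3. **Reconstruction class specificity** — mean within-class minus mean
   between-class pairwise Pearson correlation among reconstructed test
   trials. Self-pairs are excluded from the within-class average: including
   them would add r = 1 terms whose weight depends on class size.
4. **Reconstruction classifier accuracy** — the same probe trained on
   reconstructions.

Metrics 3 and 4 have **input baselines** (the same quantity on the raw
features); a representation that has truly been denoised beats its input
baseline. Chance accuracy is 1/k.

**Cohen's d cluster separation**: per class `c`,
`d_c = (D̄_w,c − D̄_b) / s`, with `D̄_w,c` the mean pairwise Euclidean
distance within class `c` (self-pairs excluded), `D̄_b` the mean distance
from class-`c` trials to all others, and `s` the standard two-sample pooled
SD of the two distance samples (the pooling is a package choice; the
definition of `s` is otherwise underdetermined). Tight clusters make the
signed value negative; summaries are reported as magnitudes (mean ± SD
across classes) for comparability with conventional effect-size tables,
with the signed per-class values retained. A zero pooled SD yields NaN,
never ±inf.

**Binary-equivalent accuracy** translates k-way probabilities to a binary
scale by counting a trial correct when its true class ranks in the top
`top_count` (e.g. 20 of 40) predictions of a one-versus-rest probe; ties
break by ascending class index.

## Protocol

* **Dimensionality sweep**: every family × bottleneck width in
  {2, 5, 10, 15, 20, 30, 50, 60, 100, 150, 200, 250, 500, 784} (capped at
  n; oversized widths are dropped with a log line). Input baselines are
  computed once per dataset. Per-cell failures are recorded and do not
  abort the sweep. Each cell's seed derives deterministically from
  (master seed, family, d, truncation fraction, replicate), so any cell is
  independently reproducible.
* **Optimal width** = argmax of reconstruction class specificity (ties
  toward the smaller width). This criterion balances task-relevant
  information extraction against compression and is meaningful in the
  native input space.
* **Truncation study**: at the selected width, retrain after removing
  {10, 30, 50, 70, 90, 95, 98}% of the training trials. Truncation is
  class-stratified uniform sampling — it preserves the 1/k chance level and
  cannot empty a class — and the retained index set for a given
  (fraction, replicate) is identical for all families. At the most extreme
  level, multiple independent jack-knife resamplings (50 by convention) of
  the retained 2% quantify variability; metrics are always computed on the
  full test split.
* **Statistics**: one-way repeated-measures ANOVA per metric over the
  matched replicates (factor: model family), computed from the textbook
  within-subject decomposition, with Greenhouse–Geisser corrected and
  uncorrected p-values both reported (sphericity over a 4-level factor is
  not guaranteed; ε from the double-centered covariance), followed by
  planned paired contrasts of TRACE against each other family. Degenerate
  tables (all families identical) return F = 0 rather than an error.
* **Shuffled-label control**: TRACE is retrained on uniformly permuted
  training labels and evaluated (Cohen's d) against independently permuted
  test labels. Both effect sizes should be ≈ 0 — the supervised objective
  must not impose class structure where none exists. The control is defined
  only for TRACE; the other families ignore labels, so it is an explicit
  unsupported operation for them.

## Synthetic data generator

`generate_synthetic` draws each trial as

    x = prototype(class)·prototype_scale + z·B·irrelevant_scale + ε·noise_sd

with one standard-Gaussian prototype per class, `z ~ N(0, I_r)` trial-level
latents mixed through a shared Gaussian loading matrix `B` (r =
`irrelevant_rank`, normalized so the mixture's per-feature SD ≈
`irrelevant_scale`), and i.i.d. Gaussian noise. Train and test share the
prototypes and loadings but not the trial-level draws; labels are exactly
balanced; everything is bit-reproducible from the spec seed.

The defaults (k = 10 classes × 120 exemplars, n = 784 features,
prototype_scale 1.0, irrelevant_rank 20, irrelevant_scale 2.0, noise_sd 1.0)
emulate the regime the method targets: roughly 1.5 training samples per
input dimension — the scale of a severely truncated image benchmark or of a
single subject's fMRI session — with shared task-irrelevant structure
contributing about four times the variance of the class signal. In that
regime unsupervised compression at d = 2 locks onto the nuisance factors
while the supervised bottleneck does not, which is the behavior under test.

What the generator does **not** emulate: spatial autocorrelation between
voxels/pixels, non-Gaussian and heteroscedastic noise, class-dependent
nuisance structure, temporal drift, or domain shift between subjects.
Passing tests on this fixture therefore demonstrate the algorithmic claims
(ordering of models, null behavior of controls, exact metric arithmetic),
not performance on any particular real dataset.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
1,200-sample / 784-feature study scale for the headline comparison (networks
trained 30 epochs, which is past the early-stopping plateau at this data
size), and smaller fixtures (n = 30–100) elsewhere. The shuffled-label
control uses 10 seeds at m = 1,000 test trials, where the sampling noise of
a null Cohen's d magnitude is comfortably below the 0.05 reporting band.

## Known limitations

* No convolutional or deeper variants, no GAN-family comparisons, and no
  hyperparameter search; the architecture is deliberately minimal so the
  effect of the classifier head is not confounded by capacity differences.
* The post-hoc probe is multinomial by default; one-versus-rest is available
  and used for the top-k binary-equivalent translation.
* Full-data dimension sweeps produce point values only (one model per cell);
  inference is confined to the replicated truncation study.
* `class_specificity` builds the full m × m correlation matrix; for very
  large test splits (≫10⁴ trials) evaluate on a subsample.
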
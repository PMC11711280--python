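# tracebench

Task-relevant autoencoding (TRACE) for feature-rich, exemplar-poor data, with
a complete model-comparison harness.

## The problem

In human neuroimaging and similar biological data, the representations worth
finding are the ones relevant to the subject's behavior — yet a single
subject's dataset may have thousands of input dimensions (voxels) and only a
few thousand trials, most of whose variance is structured, task-irrelevant
signal. Unsupervised dimensionality reduction (PCA, autoencoders, VAEs)
compresses whatever dominates the variance, which in this regime is often
exactly the nuisance structure. TRACE is a minimal supervised fix: a
one-hidden-layer autoencoder whose bottleneck also feeds a softmax
classifier, trained on

    L = L_R + α·L_CE

where `L_R = (1/(m·n)) Σ (X̂ − X)²` is the mean-squared reconstruction error
and `L_CE = −(1/m) Σ_i Σ_c y_ci log ŷ_ci` the categorical cross-entropy of
the classifier head. The classifier term pulls the `d`-dimensional bottleneck
toward class-discriminative directions; at `α = 0` the model is exactly a
standard autoencoder, the natural complexity-matched baseline. Because the
decoder maps the cleaned bottleneck back to the native input space, TRACE
also yields denoised patterns in original coordinates (e.g. voxel space) —
useful when downstream applications, such as decoded neurofeedback, need
target patterns there.

The package provides:

* `tracebench.models` — TRACE, AE, VAE, PCA behind one
  `fit` / `encode` / `reconstruct` interface (NumPy networks, reproducible
  to the bit under a fixed seed);
* `tracebench.metrics` — reconstruction fidelity, bottleneck / reconstruction
  classifier accuracy (independent logistic probes), class specificity
  (within- minus between-class pairwise Pearson r) with input baselines,
  per-class Cohen's d on pairwise Euclidean distances, and a top-k
  binary-equivalent accuracy translation;
* `tracebench.benchmark` — bottleneck-width sweeps, optimal-width selection,
  class-stratified truncation with jack-knife replicates, a shuffled-label
  null control, and repeated-measures ANOVA with planned contrasts;
* `tracebench.data` — IDX (MNIST-layout) and delimited-text readers, a
  class-structured synthetic generator, truncation and label shuffling;
* a `tracebench` CLI (`generate` / `sweep` / `report`).

## Worked example

Ten classes, 100 features, 100 exemplars per class, with a rank-10 shared
nuisance process twice as strong per feature as the class signal:

```python
from tracebench import (SyntheticSpec, SweepGrid, generate_synthetic,
                        run_sweep, select_optimal_dim)

spec = SyntheticSpec(class_count=10, feature_count=100, exemplars_per_class=100,
                     irrelevant_rank=10, seed=0)
train, test = generate_synthetic(spec)

grid = SweepGrid(bottleneck_dims=[2, 5, 10], families=["TRACE", "AE", "PCA"],
                 seed=0, model_kwargs={"epochs": 30})
result = run_sweep(grid, train, test)

cols = ["model_family", "bottleneck_dim", "bottleneck_classifier_accuracy",
        "reconstruction_class_specificity"]
print(result.to_dataframe()[cols].round(3).to_string(index=False))
print("optimal d for TRACE:", select_optimal_dim(result, "TRACE"))
```

prints

```
model_family  bottleneck_dim  bottleneck_classifier_accuracy  reconstruction_class_specificity
       TRACE               2                           0.502                             0.309
       TRACE               5                           0.901                             0.369
       TRACE              10                           0.935                             0.201
          AE               2                           0.127                             0.008
          AE               5                           0.145                             0.019
          AE              10                           0.219                             0.032
         PCA               2                           0.113                             0.009
         PCA               5                           0.137                             0.017
         PCA              10                           0.211                             0.031
optimal d for TRACE: 5
```

Reading this: a logistic probe on TRACE's 5-dimensional bottleneck decodes
the 10 classes at 90% (chance is 10%), while the same probe on AE or PCA
bottlenecks stays near chance — the unsupervised models spent their capacity
on the dominant task-irrelevant factors. TRACE's reconstruction class
specificity (0.369 at the selected width d = 5) also exceeds the raw-input
baseline (0.155 on this dataset), i.e. its reconstructions are *cleaner*
carriers of class information than the inputs themselves; AE and PCA
reconstructions are far below that baseline.

The same experiment from the shell:

```bash
tracebench generate --out-dir data/syn --classes 10 --features 100 \
    --exemplars 100 --irrelevant-rank 10 --seed 0
tracebench sweep config.yaml     # dataset/grid/training sections; see docs
tracebench report results/
```

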
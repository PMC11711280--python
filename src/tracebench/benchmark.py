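"""Experimental protocol: dimensionality sweeps, truncation grids, controls, statistics.

The protocol mirrors a model-comparison study design for sample-poor data:

1. sweep every model family over a grid of bottleneck dimensionalities and
   compute all four outcome metrics plus the input-space baselines;
2. select the "optimal" bottleneck width as the one maximizing reconstruction
   class specificity (the best balance between task-relevant information
   extraction and compression);
3. at that width, retrain under increasing training-set truncation, with
   independent jack-knife resamplings of the retained fraction at the most
   extreme level, every family seeing the identical retained trials;
4. compare families with one-way repeated-measures ANOVAs over replicates
   (Greenhouse-Geisser corrected) plus planned pairwise contrasts;
5. run a shuffled-label control (TRACE only) verifying that the supervised
   objective does not impose class structure where none exists.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import LabeledMatrix, TruncationPlan, shuffle_labels, truncate
from .metrics import (
    EffectSizeReport,
    MetricReport,
    PostHocClassifierConfig,
    class_specificity,
    cohens_d,
    posthoc_classifier_accuracy,
    reconstruction_fidelity,
)
from .models import FAMILIES, ModelConfig, TrainedModel, fit

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "SweepResult",
    "run_sweep",
    "select_optimal_dim",
    "run_truncation_study",
    "run_shuffle_control",
    "compare_models_rm_anova",
    "RMAnovaResult",
]

DEFAULT_BOTTLENECK_DIMS = (2, 5, 10, 15, 20, 30, 50, 60, 100, 150, 200, 250, 500, 784)


@dataclass
class SweepGrid:
    """The full factorial design: families x bottleneck widths (x truncation)."""

    bottleneck_dims: Sequence[int] = DEFAULT_BOTTLENECK_DIMS
    families: Sequence[str] = FAMILIES
    truncation: Optional[TruncationPlan] = None
    shuffle_control: bool = False
    seed: int = 0
    model_kwargs: dict = field(default_factory=dict)
    posthoc: PostHocClassifierConfig = field(default_factory=PostHocClassifierConfig)

    def __post_init__(self) -> None:
        dims = list(self.bottleneck_dims)
        if any(b >= a for a, b in zip(dims[1:], dims)):
            raise ValueError("bottleneck_dims must be strictly increasing")
        for f in self.families:
            if f not in FAMILIES:
                raise ValueError(f"unknown family {f!r}")


@dataclass
class SweepResult:
    """Per-cell metric and effect-size records plus provenance and failures."""

    records: list[dict] = field(default_factory=list)
    effect_sizes: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def effect_sizes_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.effect_sizes)

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "metrics.csv", index=False)
        self.effect_sizes_dataframe().to_csv(directory / "effect_sizes.csv", index=False)
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )
        (directory / "failures.json").write_text(json.dumps(self.failures, indent=2))


def cell_seed(master_seed: int, family: str, d: int, fraction: float, replicate: int) -> int:
    """Deterministic per-cell seed so every grid cell is independently reproducible."""
    key = (FAMILIES.index(family), int(d), int(round(fraction * 1000)), int(replicate))
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _input_baselines(
    train: LabeledMatrix, test: LabeledMatrix, posthoc: PostHocClassifierConfig
) -> tuple[float, float]:
    spec = class_specificity(test.features, test.labels)
    acc = posthoc_classifier_accuracy(
        train.features, train.labels, test.features, test.labels, posthoc
    )
    return spec, acc


def evaluate_cell(
    model: TrainedModel,
    train: LabeledMatrix,
    test: LabeledMatrix,
    posthoc: PostHocClassifierConfig,
    input_baselines: tuple[float, float],
    truncation_fraction: float = 0.0,
    replicate: int = 0,
) -> tuple[MetricReport, EffectSizeReport, EffectSizeReport]:
    """All four outcome metrics plus bottleneck/reconstruction effect sizes."""
    z_train = model.encode(train.features)
    z_test = model.encode(test.features)
    r_train = model.reconstruct(train.features)
    r_test = model.reconstruct(test.features)

    report = MetricReport(
        model_family=model.family,
        bottleneck_dim=model.config.bottleneck_dim,
        reconstruction_fidelity=reconstruction_fidelity(test.features, r_test),
        bottleneck_classifier_accuracy=posthoc_classifier_accuracy(
            z_train, train.labels, z_test, test.labels, posthoc
        ),
        reconstruction_class_specificity=class_specificity(r_test, test.labels),
        reconstruction_classifier_accuracy=posthoc_classifier_accuracy(
            r_train, train.labels, r_test, test.labels, posthoc
        ),
        input_class_specificity=input_baselines[0],
        input_classifier_accuracy=input_baselines[1],
        truncation_fraction=truncation_fraction,
        replicate=replicate,
    )
    efs_b = cohens_d(z_test, test.labels)
    efs_b.space = "bottleneck"
    efs_r = cohens_d(r_test, test.labels)
    efs_r.space = "reconstruction"
    return report, efs_b, efs_r


def _effect_row(efs: EffectSizeReport, family: str, d: int, fraction: float, replicate: int) -> dict:
    return {
        "model_family": family,
        "bottleneck_dim": d,
        "truncation_fraction": fraction,
        "replicate": replicate,
        "space": efs.space,
        "mean_abs": efs.mean_abs,
        "sd_abs": efs.sd_abs,
        "mean_signed": efs.mean_signed,
        "per_class": json.dumps([round(v, 10) for v in efs.per_class]),
    }


def _fit_and_record(
    result: SweepResult,
    family: str,
    d: int,
    train_cell: LabeledMatrix,
    test: LabeledMatrix,
    grid: SweepGrid,
    baselines: tuple[float, float],
    fraction: float,
    replicate: int,
) -> None:
    try:
        config = ModelConfig(
            family=family,
            input_dim=train_cell.n_features,
            bottleneck_dim=d,
            class_count=train_cell.class_count,
            seed=cell_seed(grid.seed, family, d, fraction, replicate),
            **grid.model_kwargs,
        )
        model = fit(config, train_cell)
        report, efs_b, efs_r = evaluate_cell(
            model, train_cell, test, grid.posthoc, baselines, fraction, replicate
        )
        result.records.append(report.to_dict())
        result.effect_sizes.append(_effect_row(efs_b, family, d, fraction, replicate))
        result.effect_sizes.append(_effect_row(efs_r, family, d, fraction, replicate))
        logger.info("cell family=%s d=%d fraction=%.2f replicate=%d done",
                    family, d, fraction, replicate)
    except Exception as exc:  # isolate per-cell failures; sweep continues
        logger.warning("cell family=%s d=%d fraction=%.2f replicate=%d failed: %s",
                       family, d, fraction, replicate, exc)
        result.failures.append({
            "model_family": family, "bottleneck_dim": d,
            "truncation_fraction": fraction, "replicate": replicate,
            "error": f"{type(exc).__name__}: {exc}",
        })


def run_sweep(grid: SweepGrid, train: LabeledMatrix, test: LabeledMatrix) -> SweepResult:
    """Fit every (family, bottleneck width) cell and compute all metrics.

    Input baselines are computed once per dataset (they do not depend on the
    bottleneck width). Widths exceeding the feature count are dropped with a
    log line. Per-cell errors are recorded and do not abort the sweep.
    """
    result = SweepResult(provenance={
        "seed": grid.seed,
        "families": list(grid.families),
        "bottleneck_dims": list(grid.bottleneck_dims),
        "model_kwargs": dict(grid.model_kwargs),
        "n_train": train.n_trials,
        "n_test": test.n_trials,
        "n_features": train.n_features,
        "class_count": train.class_count,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })
    baselines = _input_baselines(train, test, grid.posthoc)
    dims = [d for d in grid.bottleneck_dims if d <= train.n_features]
    for d in set(grid.bottleneck_dims) - set(dims):
        logger.info("dropping bottleneck_dim %d > feature count %d", d, train.n_features)
    for family in grid.families:
        for d in dims:
            _fit_and_record(result, family, d, train, test, grid, baselines, 0.0, 0)
    return result


def select_optimal_dim(result: SweepResult, family: str) -> int:
    """Bottleneck width maximizing reconstruction class specificity for ``family``.

    Ties break toward the smaller width (more compression).
    """
    df = result.to_dataframe()
    df = df[df["model_family"] == family]
    if len(df) < 2:
        raise ValueError("need at least two bottleneck widths to select an optimum")
    if df["reconstruction_class_specificity"].isna().any():
        raise ValueError("reconstruction class specificity missing in at least one cell")
    df = df.sort_values("bottleneck_dim")
    best = df["reconstruction_class_specificity"].max()
    return int(df.loc[df["reconstruction_class_specificity"] == best, "bottleneck_dim"].iloc[0])


def run_truncation_study(
    train: LabeledMatrix,
    test: LabeledMatrix,
    bottleneck_dim: int,
    fractions: Sequence[float] = (0.10, 0.30, 0.50, 0.70, 0.90, 0.95, 0.98),
    replicates: Union[int, dict] = 1,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    model_kwargs: Optional[dict] = None,
    posthoc: Optional[PostHocClassifierConfig] = None,
) -> SweepResult:
    """Retrain every family at a fixed bottleneck width under increasing truncation.

    ``replicates`` is the number of independent jack-knife resamplings per
    fraction (an int for all fractions or a {fraction: count} mapping, e.g.
    50 at the 0.98 level). Metrics are always computed on the full held-out
    test split, and every family trains on the identical retained sample for
    a given (fraction, replicate).
    """
    grid = SweepGrid(
        bottleneck_dims=[bottleneck_dim],
        families=families,
        seed=seed,
        model_kwargs=model_kwargs or {},
        posthoc=posthoc or PostHocClassifierConfig(),
    )
    result = SweepResult(provenance={
        "seed": seed,
        "bottleneck_dim": bottleneck_dim,
        "fractions": list(fractions),
        "replicates": replicates if isinstance(replicates, int) else dict(replicates),
        "families": list(families),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })
    baselines = _input_baselines(train, test, grid.posthoc)
    for fraction in fractions:
        n_rep = replicates.get(fraction, 1) if isinstance(replicates, dict) else replicates
        plan = TruncationPlan(fraction_removed=fraction, replicate_count=n_rep, seed=seed)
        for rep in range(n_rep):
            train_cell = truncate(train, plan, rep)
            for family in families:
                _fit_and_record(result, family, bottleneck_dim, train_cell, test,
                                grid, baselines, fraction, rep)
    return result


def run_shuffle_control(
    config: ModelConfig,
    train: LabeledMatrix,
    test: LabeledMatrix,
    shuffle_seed: Optional[int] = None,
) -> tuple[EffectSizeReport, EffectSizeReport]:
    """Label-shuffle null control: train TRACE on permuted labels and measure
    Cohen's d against independently permuted test labels.

    If the supervised objective does not hallucinate structure, both the
    bottleneck and reconstruction effect sizes should be ~0. Only TRACE uses
    labels during training, so the control is defined for TRACE alone.
    """
    if config.family != "TRACE":
        raise ValueError(
            "the shuffled-label control is only defined for TRACE: "
            "other families ignore labels during training"
        )
    base = config.seed if shuffle_seed is None else shuffle_seed
    train_shuffled = shuffle_labels(train, seed=base)
    test_shuffled = shuffle_labels(test, seed=base + 1)
    model = fit(config, train_shuffled)
    efs_b = cohens_d(model.encode(test_shuffled.features), test_shuffled.labels)
    efs_b.space = "bottleneck"
    efs_r = cohens_d(model.reconstruct(test_shuffled.features), test_shuffled.labels)
    efs_r.space = "reconstruction"
    return efs_b, efs_r


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA with planned pairwise contrasts."""

    F: float
    df1: float
    df2: float
    p_uncorrected: float
    gg_epsilon: float
    p_gg: float
    contrasts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def compare_models_rm_anova(
    per_replicate: pd.DataFrame,
    dv: str = "value",
    within: str = "model_family",
    subject: str = "replicate",
    baseline: str = "TRACE",
) -> RMAnovaResult:
    """One-way within-subject ANOVA over matched replicates, plus contrasts.

    ``per_replicate`` is long-format with one row per (replicate, family);
    replicates must be matched across families (same retained training
    samples). Reports the uncorrected p and a Greenhouse-Geisser corrected p,
    followed by planned paired contrasts of ``baseline`` against every other
    family.
    """
    wide = per_replicate.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced replicate x family table")
    Y = wide.to_numpy(dtype=np.float64)
    n, k = Y.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 families and >= 2 replicates")
    gm = Y.mean()
    ss_model = n * np.sum((Y.mean(axis=0) - gm) ** 2)
    ss_subject = k * np.sum((Y.mean(axis=1) - gm) ** 2)
    ss_total = np.sum((Y - gm) ** 2)
    ss_error = max(ss_total - ss_model - ss_subject, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_model <= 1e-300:
        F, p = 0.0, 1.0
    elif ss_error <= 1e-300:
        F, p = float("inf"), 0.0
    else:
        F = (ss_model / df1) / (ss_error / df2)
        p = float(stats.f.sf(F, df1, df2))
    eps = _gg_epsilon(Y)
    if np.isfinite(F) and F > 0:
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    else:
        p_gg = p
    contrasts = []
    if baseline in wide.columns:
        base_vals = wide[baseline].to_numpy()
        for fam in wide.columns:
            if fam == baseline:
                continue
            other = wide[fam].to_numpy()
            diff = base_vals - other
            if np.allclose(diff, 0):
                t, pt = 0.0, 1.0
            else:
                t, pt = stats.ttest_rel(base_vals, other)
            contrasts.append({
                "comparison": f"{baseline} vs {fam}",
                "t": float(t),
                "df": n - 1,
                "p": float(pt),
                "mean_difference": float(diff.mean()),
                "direction": baseline if diff.mean() > 0 else (fam if diff.mean() < 0 else "none"),
            })
    return RMAnovaResult(F=float(F), df1=float(df1), df2=float(df2),
                         p_uncorrected=float(p), gg_epsilon=float(eps), p_gg=p_gg,
                         contrasts=contrasts)


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance matrix."""
    k = Y.shape[1]
    S = np.cov(Y, rowvar=False)
    if not np.all(np.isfinite(S)) or np.allclose(S, 0):
        return 1.0
    row = S.mean(axis=0)
    gm = S.mean()
    Sc = S - row[:, None] - row[None, :] + gm
    denom = (k - 1) * np.sum(Sc**2)
    if denom <= 0:
        return 1.0
    eps = (np.trace(Sc)) ** 2 / denom
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))
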
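"""Dataset ingestion, normalization, truncation, label shuffling, and synthetic generation.

Every dataset is carried as a :class:`LabeledMatrix`: an ``m x n`` matrix of
trial feature vectors (image pixels, voxel activations, ...) plus one integer
class label per trial. Image data arrive in the IDX binary layout used by the
MNIST / Fashion MNIST distributions; tabular "voxel pattern" data arrive as
delimited text. A synthetic generator produces class-structured matrices
(class prototypes + shared task-irrelevant latent structure + noise) so the
whole pipeline runs without any download.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "LabeledMatrix",
    "SyntheticSpec",
    "TruncationPlan",
    "read_idx",
    "read_delimited",
    "write_delimited",
    "generate_synthetic",
    "truncate",
    "shuffle_labels",
]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


@dataclass
class LabeledMatrix:
    """An ``m x n`` feature matrix with one integer class label per trial.

    Labels are 0-based internally; ``class_count`` is the number of distinct
    classes ``k`` and every label must lie in ``{0..k-1}``.
    """

    features: np.ndarray
    labels: np.ndarray
    class_count: int
    split_tag: str = "train"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError(
                f"label count {self.labels.shape} does not match "
                f"trial count {self.features.shape[0]}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.class_count):
            raise ValueError("labels must lie in {0..class_count-1}")
        if self.split_tag not in ("train", "test"):
            raise ValueError("split_tag must be 'train' or 'test'")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def replace(self, **kwargs) -> "LabeledMatrix":
        d = dict(
            features=self.features,
            labels=self.labels,
            class_count=self.class_count,
            split_tag=self.split_tag,
        )
        d.update(kwargs)
        return LabeledMatrix(**d)


@dataclass
class SyntheticSpec:
    """Generative recipe for class-structured data.

    Each trial is ``prototype(class) + shared irrelevant structure + noise``:

    * one Gaussian prototype per class, scaled by ``prototype_scale`` — the
      task-relevant signal;
    * a random linear mixture of ``irrelevant_rank`` latent factors shared by
      all classes, with per-feature standard deviation ``irrelevant_scale`` —
      structured variance that carries no class information (the analogue of
      task-irrelevant signals in neuroimaging data);
    * i.i.d. Gaussian noise with standard deviation ``noise_sd``.

    Defaults emulate the severely sample-poor regime the method targets:
    10 classes x 120 exemplars = 1,200 training trials of 784 features, with
    shared task-irrelevant structure dominating the total variance.
    """

    class_count: int = 10
    feature_count: int = 784
    exemplars_per_class: int = 120
    prototype_scale: float = 1.0
    irrelevant_rank: int = 20
    irrelevant_scale: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_count < 1 or self.feature_count < 1:
            raise ValueError("class_count and feature_count must be positive")
        if self.exemplars_per_class < 2:
            raise ValueError(
                "exemplars_per_class must be >= 2 (within-class statistics undefined otherwise)"
            )
        if min(self.prototype_scale, self.irrelevant_scale, self.noise_sd) < 0:
            raise ValueError("all scales must be >= 0")
        if not 0 <= self.irrelevant_rank < self.feature_count:
            raise ValueError("irrelevant_rank must satisfy 0 <= rank < feature_count")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


@dataclass
class TruncationPlan:
    """Class-stratified removal of a fraction of the training trials.

    ``replicate_count`` independent random sub-samples ("jack-knife
    replications") are available per fraction; replicate ``r`` maps
    deterministically to a distinct retained index set under ``seed``.
    """

    fraction_removed: float
    replicate_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_removed < 1.0:
            raise ValueError("fraction_removed must lie in [0, 1)")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def read_idx(path_images: Union[str, Path], path_labels: Union[str, Path]) -> LabeledMatrix:
    """Read an IDX image/label file pair (MNIST distribution layout).

    Images are flattened row-major to ``n = rows*cols`` features and pixel
    values are scaled to [0, 1] by dividing by 255.
    """
    images = _read_idx_images(Path(path_images))
    labels = _read_idx_labels(Path(path_labels))
    if images.shape[0] != labels.shape[0]:
        raise FormatError(
            f"image count {images.shape[0]} != label count {labels.shape[0]}"
        )
    labels, k = _relabel(labels)
    return LabeledMatrix(features=images, labels=labels, class_count=k)


def _read_idx_images(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    if len(raw) < 16:
        raise FormatError(f"{path}: truncated IDX image header")
    magic, count, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != _IDX_IMAGE_MAGIC:
        raise FormatError(f"{path}: bad IDX image magic number {magic:#010x}")
    expected = 16 + count * rows * cols
    if len(raw) != expected:
        raise FormatError(f"{path}: expected {expected} bytes, found {len(raw)}")
    pixels = np.frombuffer(raw, dtype=np.uint8, offset=16)
    return pixels.reshape(count, rows * cols).astype(np.float64) / 255.0


def _read_idx_labels(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    if len(raw) < 8:
        raise FormatError(f"{path}: truncated IDX label header")
    magic, count = struct.unpack(">II", raw[:8])
    if magic != _IDX_LABEL_MAGIC:
        raise FormatError(f"{path}: bad IDX label magic number {magic:#010x}")
    if len(raw) != 8 + count:
        raise FormatError(f"{path}: expected {8 + count} bytes, found {len(raw)}")
    return np.frombuffer(raw, dtype=np.uint8, offset=8).astype(np.int64)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary integer labels (e.g. 1-based) onto {0..k-1}."""
    classes, remapped = np.unique(labels, return_inverse=True)
    return remapped.astype(np.int64), len(classes)


def read_delimited(
    path: Union[str, Path],
    label_column: Union[str, int] = "label",
    delimiter: Optional[str] = None,
    standardize: bool = False,
    standardize_moments: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> LabeledMatrix:
    """Read a delimited numeric matrix with an integer class-label column.

    ``label_column`` may be a header name or a 0-based column index (an
    ``int`` selects by position and implies a headerless file). With
    ``standardize=True`` features are per-feature z-scored; pass
    ``standardize_moments=(mean, sd)`` to apply training-split moments to a
    test split instead of the file's own.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    header = None if isinstance(label_column, int) else 0
    try:
        df = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed delimited file: {exc}") from exc
    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise FormatError(f"{path}: no column named {label_column!r}")
        label_name = label_column
    raw_labels = df[label_name].to_numpy()
    if not np.all(raw_labels == np.floor(raw_labels)):
        raise FormatError(f"{path}: label column {label_name!r} is not integer-valued")
    feat_df = df.drop(columns=[label_name])
    try:
        features = feat_df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric feature cell: {exc}") from exc
    if np.isnan(features).any():
        raise FormatError(f"{path}: missing or non-numeric feature cell")
    labels, k = _relabel(raw_labels.astype(np.int64))
    if standardize:
        if standardize_moments is not None:
            mean, sd = standardize_moments
        else:
            mean = features.mean(axis=0)
            sd = features.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        features = (features - mean) / sd
    return LabeledMatrix(features=features, labels=labels, class_count=k)


def write_delimited(data: LabeledMatrix, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a :class:`LabeledMatrix` as delimited text (round-trips with
    :func:`read_delimited` at full printed precision)."""
    path = Path(path)
    df = pd.DataFrame(data.features, columns=[f"f{j}" for j in range(data.n_features)])
    df["label"] = data.labels
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def generate_synthetic(spec: SyntheticSpec) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Generate matched train/test splits from one :class:`SyntheticSpec`.

    Prototypes and factor loadings are drawn once and shared by both splits
    (identical generative parameters); trial-level latents and noise are
    independent between splits. Bit-reproducible under ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    param_ss, train_ss, test_ss = root.spawn(3)
    rng = np.random.default_rng(param_ss)
    k, n, r = spec.class_count, spec.feature_count, spec.irrelevant_rank
    prototypes = rng.standard_normal((k, n)) * spec.prototype_scale
    if r > 0:
        # per-feature variance of the mixed factors ~= irrelevant_scale**2
        loadings = rng.standard_normal((r, n)) * (spec.irrelevant_scale / np.sqrt(r))
    else:
        loadings = np.zeros((0, n))
    train = _draw_split(spec, prototypes, loadings, np.random.default_rng(train_ss), "train")
    test = _draw_split(spec, prototypes, loadings, np.random.default_rng(test_ss), "test")
    return train, test


def _draw_split(
    spec: SyntheticSpec,
    prototypes: np.ndarray,
    loadings: np.ndarray,
    rng: np.random.Generator,
    tag: str,
) -> LabeledMatrix:
    k, n, r = spec.class_count, spec.feature_count, spec.irrelevant_rank
    m = k * spec.exemplars_per_class
    labels = np.repeat(np.arange(k), spec.exemplars_per_class)
    X = prototypes[labels].copy()
    if r > 0:
        X += rng.standard_normal((m, r)) @ loadings
    if spec.noise_sd > 0:
        X += rng.standard_normal((m, n)) * spec.noise_sd
    return LabeledMatrix(features=X, labels=labels, class_count=k, split_tag=tag)


def _replicate_rng(plan: TruncationPlan, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(plan.seed, spawn_key=(int(replicate),))
    )


def truncate(data: LabeledMatrix, plan: TruncationPlan, replicate: int = 0) -> LabeledMatrix:
    """Class-stratified random retention of ``1 - fraction_removed`` of the trials.

    The retained index set depends only on ``(plan.seed, replicate)`` and the
    label layout, so every model family trains on the identical sub-sample.
    """
    if replicate >= plan.replicate_count or replicate < 0:
        raise ValueError(
            f"replicate {replicate} out of range for replicate_count {plan.replicate_count}"
        )
    if plan.fraction_removed == 0.0:
        return data
    rng = _replicate_rng(plan, replicate)
    keep_frac = 1.0 - plan.fraction_removed
    retained: list[np.ndarray] = []
    for c in range(data.class_count):
        idx = np.flatnonzero(data.labels == c)
        n_keep = int(round(idx.size * keep_frac))
        if n_keep < 1:
            raise ValueError(
                f"truncation at fraction {plan.fraction_removed} would empty class {c}"
            )
        retained.append(rng.choice(idx, size=n_keep, replace=False))
    keep = np.sort(np.concatenate(retained))
    return data.replace(features=data.features[keep], labels=data.labels[keep])


def shuffle_labels(data: LabeledMatrix, seed: int) -> LabeledMatrix:
    """Uniform random permutation of the labels; features untouched.

    Destroys any feature-label association while preserving the label
    marginal exactly — the null control for a label-supervised model.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_trials)
    return data.replace(labels=data.labels[perm])
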
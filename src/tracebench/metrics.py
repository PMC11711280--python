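"""Outcome metrics: fidelity, class specificity, probe accuracy, effect sizes.

Four metrics quantify what a fitted model has learned, always on the held-out
test split:

* **reconstruction fidelity** — mean per-trial Pearson correlation between
  each test input and its reconstruction;
* **bottleneck classifier accuracy** — accuracy of an L2-regularized logistic
  regression probe trained (after, and independently of, the main model) on
  bottleneck activations;
* **reconstruction class specificity** — mean within-class minus mean
  between-class pairwise Pearson correlation of the reconstructions;
* **reconstruction classifier accuracy** — the same probe trained on
  reconstructions.

The latter two have input-space baselines (the same quantities on the raw
features) that a successful denoiser must beat. Cluster tightness is further
quantified by a per-class Cohen's d contrasting within- versus between-class
pairwise Euclidean distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "PostHocClassifierConfig",
    "MetricReport",
    "EffectSizeReport",
    "reconstruction_fidelity",
    "class_specificity",
    "posthoc_classifier_accuracy",
    "cohens_d",
    "binary_equivalent_accuracy",
]


@dataclass
class PostHocClassifierConfig:
    """Settings for the evaluation probe (multinomial logistic regression).

    ``lambda_l2`` is a fixed constant, identical across all models and
    representation spaces, so metric differences reflect the representations
    rather than probe tuning. ``one_vs_rest`` switches to a one-versus-all
    ensemble (used for the top-k binary-equivalent analysis on 40-class data).
    """

    lambda_l2: float = 1.0
    max_iterations: int = 1000
    tolerance: float = 1e-4
    seed: int = 0
    one_vs_rest: bool = False

    def __post_init__(self) -> None:
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be >= 0")


@dataclass
class MetricReport:
    """The four outcome metrics plus input baselines for one grid cell."""

    model_family: str
    bottleneck_dim: int
    reconstruction_fidelity: float
    bottleneck_classifier_accuracy: float
    reconstruction_class_specificity: float
    reconstruction_classifier_accuracy: float
    input_class_specificity: float
    input_classifier_accuracy: float
    truncation_fraction: float = 0.0
    replicate: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EffectSizeReport:
    """Per-class Cohen's d plus across-class summary for one representation space.

    ``per_class`` keeps the signed values of the distance contrast
    (within minus between: negative for tight clusters); the summary is
    reported on magnitudes for comparability with conventional positive
    effect-size tables.
    """

    space: str  # bottleneck | reconstruction | input
    per_class: list[float] = field(default_factory=list)
    mean_abs: float = float("nan")
    sd_abs: float = float("nan")
    mean_signed: float = float("nan")

    def format_table1(self) -> str:
        return f"{self.mean_abs:.2f} ± {self.sd_abs:.2f}"


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of A and B (vector of length m)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = np.sum(Ac * Bc, axis=1)
    den = np.sqrt(np.sum(Ac**2, axis=1) * np.sum(Bc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def reconstruction_fidelity(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean per-trial Pearson correlation between inputs and reconstructions.

    Trials with zero variance in either row have undefined correlation and
    are excluded with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    r = _pearson_rows(X, X_hat)
    valid = np.isfinite(r)
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} zero-variance trial(s) from fidelity",
            RuntimeWarning,
            stacklevel=2,
        )
    if not valid.any():
        raise ValueError("no trial has a defined input/reconstruction correlation")
    return float(r[valid].mean())


def class_specificity(X_eval: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-class minus mean between-class pairwise Pearson correlation.

    All pairwise between-trial correlations are formed; self-pairs are
    excluded from the within-class average (they would contribute r = 1
    regardless of the data). Applied to reconstructions this is the
    reconstruction class specificity; applied to raw inputs it is the input
    baseline.
    """
    X_eval = np.asarray(X_eval, dtype=np.float64)
    labels = np.asarray(labels)
    if X_eval.shape[0] != labels.shape[0]:
        raise ValueError("labels length must match trial count")
    counts = np.bincount(labels)
    if (counts[counts > 0] < 2).any():
        raise ValueError("every class must have >= 2 trials")
    if (X_eval.std(axis=1) == 0).any():
        raise ValueError("zero-variance trial: pairwise correlations undefined")
    C = np.corrcoef(X_eval)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    same_u = same[iu]
    vals = C[iu]
    return float(vals[same_u].mean() - vals[~same_u].mean())


def posthoc_classifier_accuracy(
    train_repr: np.ndarray,
    train_labels: np.ndarray,
    test_repr: np.ndarray,
    test_labels: np.ndarray,
    cfg: Optional[PostHocClassifierConfig] = None,
) -> float:
    """Top-1 test accuracy of an L2 logistic regression trained on ``train_repr``.

    The probe is fit strictly after (and independently of) the main model;
    the same routine serves bottleneck accuracy (representations = bottleneck
    activations), reconstruction accuracy (= reconstructions) and the input
    baseline (= raw features).
    """
    cfg = cfg or PostHocClassifierConfig()
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = _build_probe(cfg)
    clf.fit(train_repr, train_labels)
    return float(np.mean(clf.predict(test_repr) == np.asarray(test_labels)))


def _build_probe(cfg: PostHocClassifierConfig):
    # sklearn minimizes C*sum(log-loss) + ||w||^2/2, so C = 1/lambda_l2
    C = np.inf if cfg.lambda_l2 == 0 else 1.0 / cfg.lambda_l2
    base = LogisticRegression(
        C=C, max_iter=cfg.max_iterations, tol=cfg.tolerance, random_state=cfg.seed,
    )
    return OneVsRestClassifier(base) if cfg.one_vs_rest else base


def fit_probe(train_repr: np.ndarray, train_labels: np.ndarray,
              cfg: Optional[PostHocClassifierConfig] = None):
    """Fit and return the post-hoc probe itself (for probability-based analyses)."""
    cfg = cfg or PostHocClassifierConfig()
    clf = _build_probe(cfg)
    clf.fit(train_repr, np.asarray(train_labels))
    return clf


def cohens_d(repr_matrix: np.ndarray, labels: np.ndarray) -> EffectSizeReport:
    """Per-class Cohen's d contrasting within- vs between-class Euclidean distances.

    For each class ``c``: ``d_c = (Dw_c - Db_c) / s`` where ``Dw_c`` is the
    mean pairwise distance among class-``c`` trials (self-pairs excluded),
    ``Db_c`` the mean distance between class-``c`` trials and all other
    trials, and ``s`` the two-sample pooled standard deviation of the two
    distance samples. Tight, well-separated clusters give a large negative
    signed value; the summary is reported on magnitudes. A degenerate pooled
    SD of 0 yields ``d_c = nan`` (undefined, never infinite).
    """
    X = np.asarray(repr_matrix, dtype=np.float64)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels length must match trial count")
    classes = np.unique(labels)
    per_class: list[float] = []
    for c in classes:
        mask = labels == c
        if mask.sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
        within = pdist(X[mask])
        between = cdist(X[mask], X[~mask]).ravel()
        if between.size == 0:
            raise ValueError("at least two classes are required")
        s = _pooled_sd(within, between)
        if s == 0 or not np.isfinite(s):
            per_class.append(float("nan"))
        else:
            per_class.append(float((within.mean() - between.mean()) / s))
    arr = np.asarray(per_class)
    finite = arr[np.isfinite(arr)]
    mags = np.abs(finite)
    return EffectSizeReport(
        space="unspecified",
        per_class=per_class,
        mean_abs=float(mags.mean()) if mags.size else float("nan"),
        sd_abs=float(mags.std(ddof=1)) if mags.size > 1 else float("nan"),
        mean_signed=float(finite.mean()) if finite.size else float("nan"),
    )


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    if n1 + n2 <= 2:
        return float("nan")
    va = a.var(ddof=1) if n1 > 1 else 0.0
    vb = b.var(ddof=1) if n2 > 1 else 0.0
    return float(np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)))


def binary_equivalent_accuracy(
    probabilities: np.ndarray,
    labels: np.ndarray,
    top_count: int = 20,
) -> float:
    """Fraction of trials whose true class ranks within the ``top_count``
    highest predicted probabilities (translates k-way accuracy to a binary
    scale, e.g. top 20 of 40). Ties are broken by class-index order (the
    lower index ranks higher)."""
    P = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if top_count <= 0:
        raise ValueError("top_count must be positive")
    if top_count > P.shape[1]:
        raise ValueError("top_count exceeds class count")
    logger.debug("binary_equivalent_accuracy: ties broken by ascending class index")
    # stable argsort of -P ranks equal probabilities by ascending class index
    order = np.argsort(-P, axis=1, kind="stable")
    top = order[:, :top_count]
    return float(np.mean(np.any(top == labels[:, None], axis=1)))
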
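"""TRACE and its comparison models behind one fit/encode/reconstruct interface.

TRACE (task-relevant autoencoder via classifier enhancement) is a
fully-connected autoencoder with a single tanh hidden layer on each of the
encoding and decoding arms and a softmax (multinomial logistic) classifier
head attached to the bottleneck. It is trained by mini-batch gradient descent
on the weighted objective

    L = L_R + alpha * L_CE

where ``L_R`` is the per-element mean squared reconstruction error and
``L_CE`` the categorical cross-entropy of the classifier head. ``alpha``
controls how strongly the bottleneck is pulled toward class-discriminative
(task-relevant) directions; ``alpha = 0`` reduces the objective — and, under
a shared seed, the entire training trajectory — to the standard autoencoder.

Comparison models share the layer sizes: a standard autoencoder (AE), a
diagonal-Gaussian variational autoencoder (VAE, posterior mean used at
evaluation time), and PCA (top-``d`` principal components).

The networks are implemented directly in NumPy (manual backpropagation,
Adam optimizer) so training is exactly reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
from sklearn.decomposition import PCA

from .data import LabeledMatrix

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "reconstruction_loss",
    "cross_entropy_loss",
    "trace_objective",
    "fit",
    "encode",
    "reconstruct",
    "load_model",
    "FAMILIES",
]

FAMILIES = ("TRACE", "AE", "VAE", "PCA")

_PROB_CLIP = 1e-12  # floor inside log() so cross-entropy is never infinite
_LOGVAR_CLIP = 15.0


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters for one model.

    ``hidden_dim`` defaults to 512 for 784-dimensional inputs and
    ``min(n, 1024)`` otherwise, identical across TRACE/AE/VAE so the
    comparison is complexity-matched. ``alpha`` (classifier-loss weight) is
    used only by TRACE; PCA ignores every training hyperparameter.
    """

    family: str
    input_dim: int
    bottleneck_dim: int
    hidden_dim: Optional[int] = None
    class_count: Optional[int] = None
    alpha: float = 1.0
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    output_activation: str = "auto"  # auto | linear | sigmoid
    early_stopping: bool = True
    patience: int = 10
    min_delta: float = 1e-6

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.bottleneck_dim > self.input_dim:
            raise ValueError("bottleneck_dim must be <= input_dim")
        if self.bottleneck_dim < 1:
            raise ValueError("bottleneck_dim must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.family == "TRACE" and not self.class_count:
            raise ValueError("TRACE requires class_count")
        if self.hidden_dim is None:
            self.hidden_dim = 512 if self.input_dim == 784 else min(self.input_dim, 1024)
        if self.output_activation not in ("auto", "linear", "sigmoid"):
            raise ValueError("output_activation must be auto, linear, or sigmoid")


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Per-element mean squared reconstruction error (1/(m*n)) * sum (Xhat - X)^2."""
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.mean((X_hat - X) ** 2))


def cross_entropy_loss(y_onehot: np.ndarray, y_hat: np.ndarray) -> float:
    """Categorical cross-entropy, mean over trials; probabilities floored at 1e-12."""
    y_onehot = np.asarray(y_onehot, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y_onehot.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y_onehot.shape} vs {y_hat.shape}")
    clipped = np.clip(y_hat, _PROB_CLIP, None)
    return float(-np.sum(y_onehot * np.log(clipped)) / y_onehot.shape[0])


def trace_objective(
    X: np.ndarray,
    X_hat: np.ndarray,
    y_onehot: np.ndarray,
    y_hat: np.ndarray,
    alpha: float,
) -> float:
    """Weighted sum L_R + alpha * L_CE of reconstruction and classification losses."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return reconstruction_loss(X, X_hat) + alpha * cross_entropy_loss(y_onehot, y_hat)


def one_hot(labels: np.ndarray, class_count: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], class_count))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _Adam:
    """Adam on a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric uniform fan-in initialization (U[-1/sqrt(fan_in), +1/sqrt(fan_in)])."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


@dataclass
class TrainedModel:
    """A fitted encoder/decoder (and, for TRACE, classifier head).

    ``encode`` maps inputs to the ``d``-dimensional bottleneck; ``reconstruct``
    maps them back to input space through the decoder. Both are deterministic:
    the VAE encodes with the posterior mean.
    """

    config: ModelConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)
    pca: Optional[PCA] = None
    output_activation: str = "linear"

    @property
    def family(self) -> str:
        return self.config.family

    # -- forward passes ----------------------------------------------------
    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input width {X.shape[1] if X.ndim == 2 else X.shape} "
                f"!= model input_dim {self.config.input_dim}"
            )
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X)
        if self.family == "PCA":
            return self.pca.transform(X)
        p = self.params
        h1 = np.tanh(X @ p["W1"] + p["b1"])
        return h1 @ p["W2"] + p["b2"]  # VAE: W2/b2 hold the posterior-mean head

    def decode(self, Z: np.ndarray) -> np.ndarray:
        if self.family == "PCA":
            return self.pca.inverse_transform(Z)
        p = self.params
        h2 = np.tanh(Z @ p["W3"] + p["b3"])
        out = h2 @ p["W4"] + p["b4"]
        if self.output_activation == "sigmoid":
            out = _sigmoid(out)
        return out

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.family != "TRACE":
            raise ValueError("only TRACE has a classifier head")
        p = self.params
        return _softmax(self.encode(X) @ p["Wc"] + p["bc"])

    # -- persistence -------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        """Serialize to a directory of flat arrays plus JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "config": asdict(self.config),
            "loss_trace": self.loss_trace,
            "output_activation": self.output_activation,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        arrays = dict(self.params)
        if self.family == "PCA":
            arrays = {
                "components": self.pca.components_,
                "pca_mean": self.pca.mean_,
                "explained_variance": self.pca.explained_variance_,
            }
        np.savez(directory / "params.npz", **arrays)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        config = ModelConfig(**meta["config"])
        with np.load(directory / "params.npz") as arrays:
            data = {k: arrays[k] for k in arrays.files}
        model = cls(
            config=config,
            loss_trace=list(meta["loss_trace"]),
            output_activation=meta["output_activation"],
        )
        if config.family == "PCA":
            pca = PCA(n_components=config.bottleneck_dim, svd_solver="full")
            pca.components_ = data["components"]
            pca.mean_ = data["pca_mean"]
            pca.explained_variance_ = data["explained_variance"]
            pca.n_components_ = config.bottleneck_dim
            pca.n_features_in_ = config.input_dim
            pca.whiten = False
            model.pca = pca
        else:
            model.params = data
        return model


def load_model(directory: Union[str, Path]) -> TrainedModel:
    return TrainedModel.load(directory)


def fit(config: ModelConfig, train: LabeledMatrix) -> TrainedModel:
    """Fit one model family on the training split.

    TRACE minimizes ``L_R + alpha*L_CE`` by mini-batch Adam; AE minimizes
    ``L_R`` with identical layer sizes; the VAE minimizes reconstruction MSE
    plus a per-element-normalized KL term for its diagonal-Gaussian
    bottleneck; PCA fits the top-``d`` components of the centered data. The
    same seed always yields the same fitted parameters.
    """
    if train.n_features != config.input_dim:
        raise ValueError(
            f"training data width {train.n_features} != config.input_dim {config.input_dim}"
        )
    if config.family == "TRACE" and train.class_count != config.class_count:
        raise ValueError(
            f"train.class_count {train.class_count} != config.class_count {config.class_count}"
        )
    if config.family == "PCA":
        return _fit_pca(config, train)
    return _fit_network(config, train)


def _fit_pca(config: ModelConfig, train: LabeledMatrix) -> TrainedModel:
    pca = PCA(n_components=config.bottleneck_dim, svd_solver="full")
    pca.fit(train.features)
    recon = pca.inverse_transform(pca.transform(train.features))
    loss = reconstruction_loss(train.features, recon)
    return TrainedModel(config=config, pca=pca, loss_trace=[loss], output_activation="linear")


def _resolve_output_activation(config: ModelConfig, X: np.ndarray) -> str:
    if config.output_activation != "auto":
        return config.output_activation
    # logistic output for data living in [0,1] (images), linear otherwise
    return "sigmoid" if X.min() >= 0.0 and X.max() <= 1.0 else "linear"


def _fit_network(config: ModelConfig, train: LabeledMatrix) -> TrainedModel:
    X = train.features
    m, n = X.shape
    h, d = config.hidden_dim, config.bottleneck_dim
    out_act = _resolve_output_activation(config, X)
    variational = config.family == "VAE"
    with_head = config.family == "TRACE"
    alpha = config.alpha if with_head else 0.0
    Y = one_hot(train.labels, config.class_count) if with_head else None

    root = np.random.SeedSequence(config.seed)
    init_ss, shuffle_ss, noise_ss = root.spawn(3)
    init_rng = np.random.default_rng(init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    noise_rng = np.random.default_rng(noise_ss)

    # draw order: encoder, decoder, then (TRACE) head, then (VAE) logvar head,
    # so families sharing a seed share encoder/decoder initializations
    p: dict[str, np.ndarray] = {}
    p["W1"], p["b1"] = _init_linear(init_rng, n, h)
    p["W2"], p["b2"] = _init_linear(init_rng, h, d)
    p["W3"], p["b3"] = _init_linear(init_rng, d, h)
    p["W4"], p["b4"] = _init_linear(init_rng, h, n)
    if with_head:
        p["Wc"], p["bc"] = _init_linear(init_rng, d, config.class_count)
    if variational:
        p["W2v"], p["b2v"] = _init_linear(init_rng, h, d)

    names = sorted(p)
    opt = _Adam([p[k] for k in names], lr=config.learning_rate)

    batch = min(config.batch_size, m)
    loss_trace: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, batch):
            idx = order[start:start + batch]
            Xb = X[idx]
            Yb = Y[idx] if with_head else None
            loss, grads = _forward_backward(
                p, Xb, Yb, alpha, out_act, with_head, variational, noise_rng
            )
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"{config.family}: non-finite training loss at epoch {epoch}"
                )
            epoch_loss += loss * len(idx)
            opt.step([grads[k] for k in names])
        epoch_loss /= m
        loss_trace.append(epoch_loss)
        if config.early_stopping:
            if epoch_loss < best - config.min_delta:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    return TrainedModel(config=config, params=p, loss_trace=loss_trace,
                        output_activation=out_act)


def _forward_backward(
    p: dict[str, np.ndarray],
    X: np.ndarray,
    Y: Optional[np.ndarray],
    alpha: float,
    out_act: str,
    with_head: bool,
    variational: bool,
    noise_rng: np.random.Generator,
) -> tuple[float, dict[str, np.ndarray]]:
    m, n = X.shape
    h1 = np.tanh(X @ p["W1"] + p["b1"])
    mu = h1 @ p["W2"] + p["b2"]
    if variational:
        logvar = np.clip(h1 @ p["W2v"] + p["b2v"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        sd = np.exp(0.5 * logvar)
        eps = noise_rng.standard_normal(mu.shape)
        z = mu + sd * eps
    else:
        z = mu
    h2 = np.tanh(z @ p["W3"] + p["b3"])
    oa = h2 @ p["W4"] + p["b4"]
    xhat = _sigmoid(oa) if out_act == "sigmoid" else oa

    loss = float(np.mean((xhat - X) ** 2))
    if with_head:
        logits = z @ p["Wc"] + p["bc"]
        probs = _softmax(logits)
        loss = loss + alpha * float(
            -np.sum(Y * np.log(np.clip(probs, _PROB_CLIP, None))) / m
        )
    if variational:
        kl = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar))
        loss = loss + float(kl) / (m * n)

    g: dict[str, np.ndarray] = {}
    dxhat = 2.0 * (xhat - X) / (m * n)
    doa = dxhat * xhat * (1.0 - xhat) if out_act == "sigmoid" else dxhat
    g["W4"] = h2.T @ doa
    g["b4"] = doa.sum(axis=0)
    dh2a = (doa @ p["W4"].T) * (1.0 - h2**2)
    g["W3"] = z.T @ dh2a
    g["b3"] = dh2a.sum(axis=0)
    dz = dh2a @ p["W3"].T
    if with_head:
        dlogits = alpha * (probs - Y) / m
        g["Wc"] = z.T @ dlogits
        g["bc"] = dlogits.sum(axis=0)
        dz = dz + dlogits @ p["Wc"].T
    if variational:
        dmu = dz + mu / (m * n)
        dlogvar = dz * eps * 0.5 * sd - 0.5 * (1.0 - np.exp(logvar)) / (m * n)
        g["W2"] = h1.T @ dmu
        g["b2"] = dmu.sum(axis=0)
        g["W2v"] = h1.T @ dlogvar
        g["b2v"] = dlogvar.sum(axis=0)
        dh1 = dmu @ p["W2"].T + dlogvar @ p["W2v"].T
    else:
        g["W2"] = h1.T @ dz
        g["b2"] = dz.sum(axis=0)
        dh1 = dz @ p["W2"].T
    dh1a = dh1 * (1.0 - h1**2)
    g["W1"] = X.T @ dh1a
    g["b1"] = dh1a.sum(axis=0)
    return loss, g


def encode(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Bottleneck representation of ``X`` (posterior mean for the VAE)."""
    return model.encode(X)


def reconstruct(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Reconstruction of ``X`` through the full encoder/decoder."""
    return model.reconstruct(X)
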
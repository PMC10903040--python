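"""Model realization and the training loop.

A :class:`Model` instantiates an :class:`~hormonet.nets.builders.ArchitectureSpec`
with seeded weight initialization and trains with mini-batch RMSprop.
The binary head minimizes binary cross-entropy on the sigmoid output;
the multiclass head minimizes categorical cross-entropy on the softmax
output.  Both use the fused head gradient (p - y) / batch for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import layers as L
from .builders import ArchitectureSpec, LayerSpec

__all__ = ["TrainConfig", "Model", "TrainingDivergedError", "train"]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 0.00025
    batch_size: int = 16
    optimizer: str = "rmsprop"
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def _realize(spec: LayerSpec, in_shape: tuple[int, ...], rng: np.random.Generator) -> L.Layer:
    k, p = spec.kind, spec.params
    if k == "conv":
        return L.Conv1D(in_shape[1], p["filters"], p["kernel"], rng,
                        activation=p.get("activation", "relu"))
    if k == "maxpool":
        return L.MaxPool1D(p.get("window", 2), p.get("stride", 2))
    if k == "batchnorm":
        return L.BatchNorm1D(in_shape[-1])
    if k == "global_average_pool":
        return L.GlobalAveragePool1D()
    if k == "flatten":
        return L.Flatten()
    if k == "lstm":
        return L.LSTMLayer(in_shape[1], p["units"], rng)
    if k == "dense":
        return L.Dense(in_shape[0], p["units"], rng, activation=p.get("activation"))
    if k == "dropout":
        return L.Dropout(p["rate"], rng)
    if k == "relu":
        return L.ReLULayer()
    if k == "output":
        return L.Dense(in_shape[0], p.get("n_classes", 1), rng, activation=None)
    raise ValueError(f"unknown layer kind {k!r}")


class Model:
    """A realized network: seeded weights over an architecture spec."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        shapes = spec.shapes()
        self.layers = [
            _realize(layer_spec, shapes[i][1], rng)
            for i, layer_spec in enumerate(spec.layers)
        ]

    # -- inference ---------------------------------------------------------

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]  # (batch, length) -> (batch, length, 1)
        return x

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self._prepare(x)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x)
        if self.spec.head == "sigmoid":
            return L.sigmoid(z[:, 0])
        return L.softmax(z, axis=-1)

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        p = self.predict_proba(x)
        if self.spec.head == "sigmoid":
            return (p >= threshold).astype(int)
        return p.argmax(axis=-1)

    # -- training ----------------------------------------------------------

    def _loss_and_headgrad(self, z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = len(y)
        if self.spec.head == "sigmoid":
            p = L.sigmoid(z[:, 0])
            loss = L.bce_loss(p, y)
            grad = ((p - y) / n)[:, None]
        else:
            p = L.softmax(z, axis=-1)
            onehot = np.eye(self.spec.n_classes)[y.astype(int)]
            loss = L.cce_loss(p, onehot)
            grad = (p - onehot) / n
        return loss, grad

    def fit(self, x: np.ndarray, y: np.ndarray,
            config: TrainConfig = TrainConfig()) -> list[dict[str, float]]:
        """Mini-batch RMSprop training; returns per-epoch history."""
        x = self._prepare(x)
        y = np.asarray(y)
        rng = np.random.default_rng(config.seed)
        opt = L.RMSprop(lr=config.learning_rate)
        history: list[dict[str, float]] = []
        n = len(y)
        for epoch in range(config.epochs):
            order = rng.permutation(n) if config.shuffle else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                xb, yb = x[idx], y[idx]
                out = xb
                for layer in self.layers:
                    out = layer.forward(out, training=True)
                loss, grad = self._loss_and_headgrad(out, yb)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, batch offset {start}"
                    )
                epoch_loss += loss * len(idx)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                for layer in self.layers:
                    if layer.params:
                        opt.step(layer.params, layer.grads)
            acc = float(np.mean(self.predict(x[..., 0] if x.shape[-1] == 1 else x) == y))
            history.append({"epoch": epoch, "loss": epoch_loss / n, "accuracy": acc})
        return history


def train(spec: ArchitectureSpec, x: np.ndarray, y: np.ndarray,
          config: TrainConfig = TrainConfig()) -> tuple[Model, list[dict[str, float]]]:
    """Build a model from ``spec`` and fit it; returns (model, history)."""
    model = Model(spec, seed=config.seed)
    history = model.fit(x, y, config)
    return model, history
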
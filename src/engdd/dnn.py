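"""Feed-forward binary classifier trained with binary cross-entropy.

A rectifier MLP ending in a single sigmoid unit, trained by Adam on
shuffled mini-batches.  Defaults: hidden stack [256, 64], 100 epochs,
batch size 64, learning rate 1e-3.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from ._mlp import MLP, AdamState, adam_step, minibatches, sigmoid
from .features import PairDataset

P_CLIP = 1e-12


@dataclass
class DnnHyperparams:
    epochs: int = 100
    batch_size: int = 64
    hidden_dims: tuple[int, ...] = (256, 64)
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.lr <= 0:
            raise ValueError("invalid hyperparameters")


@dataclass
class DnnModel:
    net: MLP
    training_history: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "DnnModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clipped away from {0,1}."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p lengths differ")
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train_dnn(dataset: PairDataset,
              hp: DnnHyperparams | None = None) -> DnnModel:
    """Train for exactly ``hp.epochs`` epochs; history holds one
    mean mini-batch loss per epoch."""
    hp = hp or DnnHyperparams()
    y = dataset.y.astype(float)
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(hp.seed)
    net = MLP([dataset.X.shape[1], *hp.hidden_dims, 1], rng)
    state = AdamState.like(net.params())
    history: list[float] = []
    n = len(dataset)
    for _ in range(hp.epochs):
        losses = []
        for batch in minibatches(n, hp.batch_size, rng):
            Xb, yb = dataset.X[batch], y[batch]
            acts, out = net._forward_cached(Xb)
            z = out[:, 0]
            p = sigmoid(z)
            # BCE on the logit: dL/dz = (p - y)/B, stable without clipping
            losses.append(float(np.mean(
                np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - yb * z)))
            grads = net.backward(acts, (p - yb) / len(batch))
            adam_step(net.params(), grads, state, hp.lr)
        history.append(float(np.mean(losses)))
    return DnnModel(net=net, training_history=history)


def predict_dnn(model: DnnModel, X: np.ndarray) -> np.ndarray:
    """Forward pass; outputs strictly inside (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.net.sizes[0]:
        raise ValueError(
            f"X width {X.shape[1]} != training width {model.net.sizes[0]}"
        )
    p = sigmoid(model.net.forward(X))
    return np.clip(p, P_CLIP, 1.0 - P_CLIP)
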
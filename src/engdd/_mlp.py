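"""Minimal dense multilayer perceptron with Adam, in pure NumPy.

Shared backbone for the boosted shallow weak learners and the
feed-forward classifier.  Hidden layers use the rectifier; the output
layer is a single linear unit (callers apply the logistic link when a
probability is needed).  Everything is deterministic given the seeds
passed in: initialisation from a Generator, batch order from a
Generator, and no threading-dependent reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function, exact for |z| up to ~700."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


@dataclass
class AdamState:
    """Per-parameter first/second moment accumulators."""

    m: list[np.ndarray]
    v: list[np.ndarray]
    t: int = 0

    @classmethod
    def like(cls, params: list[np.ndarray]) -> "AdamState":
        return cls([np.zeros_like(p) for p in params],
                   [np.zeros_like(p) for p in params])


class MLP:
    """Fully connected net: sizes[0] -> ... -> sizes[-1], linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialisation, appropriate for rectifier hiddens
            self.W.append(rng.standard_normal((fan_in, fan_out))
                          * np.sqrt(2.0 / fan_in))
            self.b.append(np.zeros(fan_out))

    # ---- parameter plumbing -------------------------------------------
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    def zero_output(self) -> None:
        """Make the net the constant-zero function (last layer zeroed)."""
        self.W[-1][:] = 0.0
        self.b[-1][:] = 0.0

    # ---- forward / backward -------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw (linear) output, shape (n,) when the output width is 1."""
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        out = a @ self.W[-1] + self.b[-1]
        return out[:, 0] if out.shape[1] == 1 else out

    def _forward_cached(self, X: np.ndarray):
        acts = [X]
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        out = a @ self.W[-1] + self.b[-1]
        return acts, out

    def backward(self, acts: list[np.ndarray], grad_out: np.ndarray,
                 l2: float = 0.0) -> list[np.ndarray]:
        """Gradients of sum(loss) w.r.t. params(), given dL/d(raw output).

        The L2 penalty applies to weights only, never biases.
        """
        if grad_out.ndim == 1:
            grad_out = grad_out[:, None]
        gW: list[np.ndarray] = [None] * len(self.W)  # type: ignore
        gb: list[np.ndarray] = [None] * len(self.b)  # type: ignore
        delta = grad_out
        for layer in range(len(self.W) - 1, -1, -1):
            gW[layer] = acts[layer].T @ delta + l2 * self.W[layer]
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * (acts[layer] > 0)
        return gW + gb


def adam_step(params: list[np.ndarray], grads: list[np.ndarray],
              state: AdamState, lr: float, beta1: float = 0.9,
              beta2: float = 0.999, eps: float = 1e-8) -> None:
    """One in-place Adam update over a flat parameter list."""
    state.t += 1
    bc1 = 1.0 - beta1 ** state.t
    bc2 = 1.0 - beta2 ** state.t
    for p, g, m, v in zip(params, grads, state.m, state.v):
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def minibatches(n: int, batch_size: int,
                rng: np.random.Generator):
    """Yield shuffled index batches covering 0..n-1 once."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
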
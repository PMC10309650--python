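"""Gradient boosting of shallow neural networks with Newton targets.

The model is an additive raw-score ensemble

    F(x) = F0 + sum_k alpha_k f_k(x),        p(x) = sigmoid(F(x)),

where F0 is the prior log-odds of the training labels and each f_k is a
small rectifier MLP with a linear output unit.  Stage t fits f_t by
weighted least squares against the second-order (Newton) residuals of
the logistic loss: with p = sigmoid(F_prev),

    g = p - y,   h = p (1 - p),   target = -g / h,   weight = h,

so already-confident samples exert vanishing pull.  The step size
alpha_t is the constant ``boost_rate``.  After each stage every learner
is jointly fine-tuned for ``correct_epoch`` epochs against the binary
cross-entropy of the full additive score (the corrective step); a guard
restores the pre-step parameters if the step degrades the training loss.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from ._mlp import MLP, AdamState, adam_step, minibatches, sigmoid
from .features import PairDataset

H_FLOOR = 1e-12  # clip on the curvature h to avoid -g/h blow-up


@dataclass
class GrownetHyperparams:
    lr: float = 0.05
    num_nets: int = 20
    batch_size: int = 64
    boost_rate: float = 1.0
    epochs_per_stage: int = 1
    correct_epoch: int = 1
    l2: float = 0.001
    hidden_dims: tuple[int, ...] = (16, 16)

    def __post_init__(self) -> None:
        if min(self.lr, self.num_nets, self.batch_size,
               self.epochs_per_stage + 1, self.l2 + 1) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class GrownetModel:
    learners: list[MLP]
    step_sizes: list[float]
    initial_score: float
    boost_rate: float
    hp: GrownetHyperparams = field(default_factory=GrownetHyperparams)

    def raw_score(self, X: np.ndarray) -> np.ndarray:
        F = np.full(X.shape[0], self.initial_score)
        for alpha, f in zip(self.step_sizes, self.learners):
            F += alpha * f.forward(X)
        return F

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "GrownetModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def boost_targets(y: np.ndarray, F: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Newton targets -g/h and weights h of the logistic loss at F."""
    y = np.asarray(y, dtype=float)
    F = np.asarray(F, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    if not np.isfinite(F).all():
        raise ValueError("raw scores must be finite")
    p = sigmoid(F)
    g = p - y
    h = np.maximum(p * (1.0 - p), H_FLOOR)
    return -g / h, h


def _bce_from_raw(y: np.ndarray, F: np.ndarray) -> float:
    """Mean logistic loss of raw scores, computed in the log domain."""
    # log(1 + e^{-|F|}) + max(F,0) - y*F  is stable for large |F|
    return float(np.mean(np.logaddexp(0.0, -np.abs(F))
                         + np.maximum(F, 0.0) - y * F))


def fit_stage(dataset: PairDataset, F_prev: np.ndarray,
              hp: GrownetHyperparams, seed: int) -> tuple[MLP, float]:
    """Train one fresh weak learner on the h-weighted Newton residuals.

    Minimises sum_i h_i (target_i - f(x_i))^2 by Adam over
    ``epochs_per_stage`` shuffled epochs.  If the trained learner is no
    better than the zero function on that objective, its output layer is
    zeroed (the stage contributes nothing rather than harm).
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if F_prev.shape[0] != n:
        raise ValueError("F_prev length mismatch")
    targets, weights = boost_targets(dataset.y, F_prev)
    rng = np.random.default_rng(seed)
    net = MLP([dataset.X.shape[1], *hp.hidden_dims, 1], rng)
    state = AdamState.like(net.params())
    for _ in range(hp.epochs_per_stage):
        for batch in minibatches(n, hp.batch_size, rng):
            Xb, tb, wb = dataset.X[batch], targets[batch], weights[batch]
            acts, out = net._forward_cached(Xb)
            resid = out[:, 0] - tb
            grad_out = (2.0 * wb * resid / len(batch))
            grads = net.backward(acts, grad_out, l2=hp.l2)
            adam_step(net.params(), grads, state, hp.lr)

    def objective(pred: np.ndarray) -> float:
        return float(np.sum(weights * (targets - pred) ** 2))

    if objective(net.forward(dataset.X)) > objective(np.zeros(n)):
        net.zero_output()
    return net, hp.boost_rate


def corrective_step(model: GrownetModel, dataset: PairDataset,
                    hp: GrownetHyperparams,
                    seed: int = 0) -> GrownetModel:
    """Jointly fine-tune all learners against the additive-score BCE.

    Runs ``correct_epoch`` epochs of Adam on every learner's parameters
    at once; if the full-data training BCE rises by more than 1e-6 the
    pre-step parameters are restored.
    """
    if not model.learners:
        raise ValueError("corrective step needs at least one learner")
    if hp.correct_epoch == 0:
        return model
    n = len(dataset)
    X, y = dataset.X, dataset.y.astype(float)
    before_params = [f.copy_params() for f in model.learners]
    before_bce = _bce_from_raw(y, model.raw_score(X))
    rng = np.random.default_rng(seed)
    states = [AdamState.like(f.params()) for f in model.learners]
    for _ in range(hp.correct_epoch):
        for batch in minibatches(n, hp.batch_size, rng):
            Xb, yb = X[batch], y[batch]
            cached = [f._forward_cached(Xb) for f in model.learners]
            F = np.full(len(batch), model.initial_score)
            for alpha, (_, out) in zip(model.step_sizes, cached):
                F += alpha * out[:, 0]
            dF = (sigmoid(F) - yb) / len(batch)
            for f, alpha, (acts, _), st in zip(
                    model.learners, model.step_sizes, cached, states):
                grads = f.backward(acts, alpha * dF, l2=hp.l2)
                adam_step(f.params(), grads, st, hp.lr)
    after_bce = _bce_from_raw(y, model.raw_score(X))
    if after_bce > before_bce + 1e-6:
        for f, p in zip(model.learners, before_params):
            f.set_params(p)
    return model


def train_grownet(dataset: PairDataset, hp: GrownetHyperparams | None = None,
                  seed: int = 0) -> GrownetModel:
    """Full boosting loop: prior log-odds, then num_nets Newton stages."""
    hp = hp or GrownetHyperparams()
    y = dataset.y
    pbar = float(np.mean(y))
    if pbar in (0.0, 1.0):
        raise ValueError("training data must contain both classes")
    F0 = float(np.log(pbar / (1.0 - pbar)))
    model = GrownetModel(learners=[], step_sizes=[], initial_score=F0,
                         boost_rate=hp.boost_rate, hp=hp)
    ss = np.random.SeedSequence(seed)
    stage_seeds = ss.generate_state(2 * hp.num_nets) % (2 ** 31)
    F = np.full(len(dataset), F0)
    for k in range(hp.num_nets):
        net, alpha = fit_stage(dataset, F, hp, int(stage_seeds[2 * k]))
        model.learners.append(net)
        model.step_sizes.append(alpha)
        corrective_step(model, dataset, hp, int(stage_seeds[2 * k + 1]))
        F = model.raw_score(dataset.X)
    return model


def predict_grownet(model: GrownetModel, X: np.ndarray) -> np.ndarray:
    """Interaction probabilities sigmoid(F0 + sum alpha_k f_k(x))."""
    X = np.asarray(X, dtype=float)
    if model.learners and X.shape[1] != model.learners[0].sizes[0]:
        raise ValueError(
            f"X width {X.shape[1]} != training width "
            f"{model.learners[0].sizes[0]}"
        )
    return sigmoid(model.raw_score(X))
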
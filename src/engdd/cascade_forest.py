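"""Cascade deep forest with class-vector augmentation.

Each cascade layer is a committee of ten tree ensembles — five random
forests (bootstrapped, square-root feature subsampling) and five
extra-trees forests (random cut-points, square-root feature
subsampling, no bootstrap) — of 100 trees each by default, unlimited
depth.  Every predictor emits a two-class
probability row, so a layer produces a 20-dimensional class vector; the
next layer consumes ``[base features || class vector]``, i.e. width
``input_dim + 20`` for every layer after the first.

Growth control: the class vectors used while growing are *cross-fitted*
(each row's probabilities come from predictors not trained on that row),
which prevents the cascade from feeding on its own training fit; the
monitored score is the cross-fitted committee accuracy, and growth stops
when a new layer fails to improve the best score seen by more than
``tolerance``, or at ``max_layers`` (20).  For prediction-time use every
layer's predictors are refit on all rows, and probabilities are read
from the committee of the best-scoring layer.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import PairDataset

CLASS_VECTOR_DIM = 20  # 10 predictors x 2 classes


@dataclass
class CascadeHyperparams:
    max_layers: int = 20
    n_estimators_per_type: int = 5
    n_trees: int = 100
    crossfit_folds: int = 3
    tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_layers, self.n_estimators_per_type, self.n_trees,
               self.crossfit_folds) < 1:
            raise ValueError("invalid hyperparameters")


@dataclass
class CascadeLayer:
    predictors: list  # 10 fitted ensembles, RF types first then ET types
    score: float      # cross-fitted committee accuracy while growing

    def class_vectors(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([p.predict_proba(X) for p in self.predictors])

    def committee_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([p.predict_proba(X)[:, 1] for p in self.predictors],
                       axis=0)


@dataclass
class CascadeModel:
    layers: list[CascadeLayer]
    best_layer: int
    input_dim: int
    hp: CascadeHyperparams = field(default_factory=CascadeHyperparams)
    use_last_layer: bool = False

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "CascadeModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _predictor_seed(seed: int, layer: int, index: int) -> int:
    ss = np.random.SeedSequence((seed, layer, index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _make_predictor(kind: str, seed: int, hp: CascadeHyperparams):
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp.n_trees, max_features="sqrt", max_depth=None,
            random_state=seed, n_jobs=1)
    return ExtraTreesClassifier(
        n_estimators=hp.n_trees, max_features="sqrt", max_depth=None,
        random_state=seed, n_jobs=1)


def layer_class_vectors(X: np.ndarray, y: np.ndarray,
                        hp: CascadeHyperparams, layer_seed: int
                        ) -> tuple[CascadeLayer, np.ndarray]:
    """Fit one layer and return its out-of-fold class matrix (n x 20).

    Each of the ten predictors is cross-fitted over stratified folds so
    row i's probabilities come from a model that never saw row i; the
    predictors kept in the layer are then refit on all rows.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes required")
    k = min(hp.crossfit_folds, int(counts.min()))
    if k < 2:
        raise ValueError(
            "minority class too small for stratified cross-fitting"
        )
    kinds = ["rf"] * hp.n_estimators_per_type + \
            ["et"] * hp.n_estimators_per_type
    oof_blocks = []
    fitted = []
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=layer_seed % (2 ** 31))
    splits = list(skf.split(X, y))
    for idx, kind in enumerate(kinds):
        seed = _predictor_seed(layer_seed, 0, idx)
        oof = np.zeros((len(y), 2))
        for tr, te in splits:
            est = _make_predictor(kind, seed, hp)
            est.fit(X[tr], y[tr])
            oof[te] = est.predict_proba(X[te])
        oof_blocks.append(oof)
        full = _make_predictor(kind, seed, hp)
        full.fit(X, y)
        fitted.append(full)
    oof_matrix = np.hstack(oof_blocks)
    committee = np.mean([b[:, 1] for b in oof_blocks], axis=0)
    score = float(np.mean((committee > 0.5).astype(int) == y))
    return CascadeLayer(predictors=fitted, score=score), oof_matrix


def train_cascade(dataset: PairDataset,
                  hp: CascadeHyperparams | None = None) -> CascadeModel:
    """Grow layers on [base features || previous class vectors]."""
    hp = hp or CascadeHyperparams()
    X_base, y = dataset.X, dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    layers: list[CascadeLayer] = []
    best_score = -np.inf
    best_layer = 0
    X_aug = X_base
    for ell in range(hp.max_layers):
        layer_seed = _predictor_seed(hp.seed, ell + 1, 997)
        layer, oof = layer_class_vectors(X_aug, y, hp, layer_seed)
        layers.append(layer)
        if layer.score > best_score + hp.tolerance:
            best_score = layer.score
            best_layer = ell
        elif ell > best_layer:
            break
        X_aug = np.hstack([X_base, oof])
    return CascadeModel(layers=layers, best_layer=best_layer,
                        input_dim=X_base.shape[1], hp=hp)


def predict_cascade(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Push X through layers 0..best_layer; mean positive-class
    probability of the final committee."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"X width {X.shape[1]} != input_dim {model.input_dim}"
        )
    last = model.n_layers - 1 if model.use_last_layer else model.best_layer
    X_aug = X
    for ell in range(last):
        X_aug = np.hstack([X, model.layers[ell].class_vectors(X_aug)])
    return model.layers[last].committee_proba(X_aug)
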
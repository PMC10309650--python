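"""Soft-vote fusion of the three base learners.

The ensemble score of a pair is

    Score = alpha * C_grownet + beta * C_dnn + gamma * C_forest,

with (alpha, beta, gamma) on the unit simplex so the score remains a
probability and the fixed 0.5 decision threshold keeps its meaning.
Weights are tuned by exhaustive grid search over the simplex lattice
(step 0.1 by default, 66 candidates), maximising AUPR on a held-out
validation slice of the training pairs; the slice honours the active
cross-validation scheme's entity-disjointness so tuning never sees a
test drug or target.  A pair is classified positive iff its score is
strictly greater than the threshold.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from . import cascade_forest as cf
from . import dnn as dnn_mod
from . import grownet as gn
from .config import RunConfig
from .data_io import FeatureTable, InteractionSet, ScoreReport
from .features import PairDataset, PcaModel, apply_pca
from .metrics import pr_auc, roc_auc


@dataclass
class EnsembleWeights:
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass
class EngddModel:
    """The full trained predictor plus the preprocessing it needs."""

    grownet: gn.GrownetModel
    dnn: dnn_mod.DnnModel
    cascade: cf.CascadeModel
    weights: EnsembleWeights
    threshold: float = 0.5
    pca_drug: PcaModel | None = None
    pca_target: PcaModel | None = None
    validation_auprs: dict[str, float] = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return soft_vote(gn.predict_grownet(self.grownet, X),
                         dnn_mod.predict_dnn(self.dnn, X),
                         cf.predict_cascade(self.cascade, X),
                         self.weights)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "EngddModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def soft_vote(p_grownet: np.ndarray, p_dnn: np.ndarray,
              p_forest: np.ndarray, w: EnsembleWeights) -> np.ndarray:
    """Elementwise weighted average of the three probability vectors."""
    pg, pd_, pf = (np.asarray(p, dtype=float)
                   for p in (p_grownet, p_dnn, p_forest))
    if not pg.shape == pd_.shape == pf.shape:
        raise ValueError("probability vectors differ in length")
    return w.alpha * pg + w.beta * pd_ + w.gamma * pf


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff score strictly exceeds the threshold."""
    return (np.asarray(scores, dtype=float) > threshold).astype(int)


def simplex_grid(grid_step: float) -> list[tuple[float, float, float]]:
    """All lattice points (a, b, c)/m with a+b+c = m = round(1/step)."""
    m = int(round(1.0 / grid_step))
    return [(a / m, b / m, (m - a - b) / m)
            for a in range(m + 1) for b in range(m - a + 1)]


def tune_weights(val_pg: np.ndarray, val_pd: np.ndarray,
                 val_pf: np.ndarray, val_y: np.ndarray,
                 grid_step: float = 0.1) -> EnsembleWeights:
    """Exhaustive simplex search maximising validation AUPR.

    Ties break by higher AUC, then lexicographically largest alpha,
    then beta — fully deterministic.
    """
    val_y = np.asarray(val_y, dtype=int)
    if len(np.unique(val_y)) < 2:
        raise ValueError("validation labels must contain both classes")
    best = None
    for (a, b, c) in simplex_grid(grid_step):
        s = a * val_pg + b * val_pd + c * val_pf
        key = (pr_auc(s, val_y), roc_auc(s, val_y), a, b)
        if best is None or key > best[0]:
            best = (key, (a, b, c))
    return EnsembleWeights(*best[1])


def _validation_split(dataset: PairDataset, scheme: str, fraction: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    """(fit indices, validation indices), entity-disjoint for cold-start
    schemes, stratified-ish for the pair scheme."""
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if scheme in ("drug", "target"):
        col = 0 if scheme == "drug" else 1
        entities = sorted({p[col] for p in dataset.pair_index})
        order = rng.permutation(len(entities))
        held: set[str] = set()
        count = 0
        for j in order:
            held.add(entities[j])
            count += sum(1 for p in dataset.pair_index if p[col] == entities[j])
            if count >= fraction * n:
                break
        val = np.array([i for i, p in enumerate(dataset.pair_index)
                        if p[col] in held], dtype=int)
    else:
        # stratified: sample within each class
        val_parts = []
        for label in (0, 1):
            idx = np.flatnonzero(dataset.y == label)
            take = max(1, int(round(fraction * len(idx))))
            val_parts.append(rng.choice(idx, size=take, replace=False))
        val = np.sort(np.concatenate(val_parts))
    fit = np.setdiff1d(np.arange(n), val)
    if len(np.unique(dataset.y[val])) < 2 or \
            len(np.unique(dataset.y[fit])) < 2:
        raise ValueError("dataset too small/skewed for a validation slice")
    return fit, val


def _fit_base_learners(dataset: PairDataset, cfg: RunConfig, seed: int
                       ) -> tuple[gn.GrownetModel, dnn_mod.DnnModel,
                                  cf.CascadeModel]:
    ss = np.random.SeedSequence((seed, 17)).generate_state(3) % (2 ** 31)
    g = gn.train_grownet(dataset, cfg.grownet, seed=int(ss[0]))
    d = dnn_mod.train_dnn(dataset, replace(cfg.dnn, seed=int(ss[1])))
    c = cf.train_cascade(dataset, replace(cfg.cascade, seed=int(ss[2])))
    return g, d, c


def train_engdd(dataset: PairDataset, cfg: RunConfig | None = None,
                scheme: str = "pair", seed: int = 0) -> EngddModel:
    """Train the three learners, tune the vote, optionally refit.

    A validation slice (default 20% of the training pairs) is held out
    for weight tuning; the learners are then refit on all training
    pairs with the tuned weights retained (``ensemble.refit``).
    """
    cfg = cfg or RunConfig()
    ecfg = cfg.ensemble
    if ecfg.weights is not None:
        weights = EnsembleWeights(*ecfg.weights)
        g, d, c = _fit_base_learners(dataset, cfg, seed)
        return EngddModel(g, d, c, weights, threshold=ecfg.threshold)
    fit_idx, val_idx = _validation_split(dataset, scheme,
                                         ecfg.val_fraction, seed)
    fit_ds, val_ds = dataset.subset(fit_idx), dataset.subset(val_idx)
    g, d, c = _fit_base_learners(fit_ds, cfg, seed)
    val_pg = gn.predict_grownet(g, val_ds.X)
    val_pd = dnn_mod.predict_dnn(d, val_ds.X)
    val_pf = cf.predict_cascade(c, val_ds.X)
    weights = tune_weights(val_pg, val_pd, val_pf, val_ds.y,
                           grid_step=ecfg.grid_step)
    fused = soft_vote(val_pg, val_pd, val_pf, weights)
    auprs = {
        "grownet": pr_auc(val_pg, val_ds.y),
        "dnn": pr_auc(val_pd, val_ds.y),
        "cascade": pr_auc(val_pf, val_ds.y),
        "ensemble": pr_auc(fused, val_ds.y),
    }
    # the grid contains the vertices, so the tuned vote cannot lose to
    # any single learner on the tuning slice
    assert auprs["ensemble"] >= max(auprs[k] for k in
                                    ("grownet", "dnn", "cascade")) - 1e-12
    if ecfg.refit:
        g, d, c = _fit_base_learners(dataset, cfg, seed)
    return EngddModel(g, d, c, weights, threshold=ecfg.threshold,
                      validation_auprs=auprs)


def rank_candidates(model: EngddModel, drugs: FeatureTable,
                    targets: FeatureTable, known: InteractionSet,
                    top_k: int | None = None, *,
                    include_known: bool = True,
                    chunk_size: int = 200_000) -> ScoreReport:
    """Score every drug x target pair and rank by descending score.

    Requires the model to carry its PCA transforms.  Pairs are scored
    in chunks so arbitrarily large grids stay within memory.
    """
    if model.pca_drug is None or model.pca_target is None:
        raise ValueError("model lacks PCA transforms; cannot score raw IDs")
    dr = apply_pca(model.pca_drug, drugs)
    tr = apply_pca(model.pca_target, targets)
    n_d, n_t = len(drugs.entity_ids), len(targets.entity_ids)
    all_d, all_t, all_s, all_k = [], [], [], []
    codes = np.arange(n_d * n_t)
    for start in range(0, len(codes), chunk_size):
        chunk = codes[start:start + chunk_size]
        di, ti = chunk // n_t, chunk % n_t
        X = np.hstack([dr[di], tr[ti]])
        scores = model.predict_proba(X)
        for c, s in zip(chunk, scores):
            d_id = drugs.entity_ids[c // n_t]
            t_id = targets.entity_ids[c % n_t]
            is_known = (d_id, t_id) in known.pairs
            if not include_known and is_known:
                continue
            all_d.append(d_id)
            all_t.append(t_id)
            all_s.append(float(s))
            all_k.append(is_known)
    report = ScoreReport.from_scores(all_d, all_t, all_s, all_k)
    if top_k is not None:
        report = ScoreReport(report.head(top_k))
    return report
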
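"""End-to-end orchestration: tables -> folds -> trained models -> metrics.

The repeated cross-validation driver mirrors the study protocol: per
repetition, a fresh 1:1 negative undersample and fresh folds are drawn;
within each fold PCA is fit on the training entities only, the ensemble
is trained on the fold's training pairs, and the fold's test pairs are
scored.  Fold predictions are pooled within a repetition before metrics
are computed; the headline numbers are means over repetitions.

The requested reduced dimension ``pca.d`` is capped at each table's
admissible maximum ``min(n_entities, n_features)`` (a 30-target table
cannot support 100 components); the cap is logged, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .data_io import FeatureTable, InteractionSet
from .ensemble import EngddModel, train_engdd
from .features import PairDataset, apply_pca, build_pairs, fit_pca
from .metrics import METRIC_NAMES, MetricsReport, all_metrics
from .sampling_cv import CVPlan, make_cv_plan, sample_negatives

logger = logging.getLogger(__name__)


def _capped_d(table: FeatureTable, d: int) -> int:
    d_max = min(table.n_entities, table.n_features)
    if d > d_max:
        logger.info("capping pca.d from %d to %d for the %s table",
                    d, d_max, table.kind)
        return d_max
    return d


def reduce_tables(drugs: FeatureTable, targets: FeatureTable,
                  cfg: RunConfig, *,
                  train_drug_ids: list[str] | None = None,
                  train_target_ids: list[str] | None = None):
    """Fit PCA on (a subset of) each table; project the whole table.

    Returns ``(drug_reduced, target_reduced, pca_drug, pca_target)``
    with reduced matrices covering *all* entities, so held-out drugs
    and targets can still be scored.
    """
    fit_drugs = drugs if train_drug_ids is None else \
        drugs.restrict(train_drug_ids)
    fit_targets = targets if train_target_ids is None else \
        targets.restrict(train_target_ids)
    pca_d = fit_pca(fit_drugs, _capped_d(fit_drugs, cfg.pca.d),
                    standardize=cfg.pca.standardize)
    pca_t = fit_pca(fit_targets, _capped_d(fit_targets, cfg.pca.d),
                    standardize=cfg.pca.standardize)
    return (apply_pca(pca_d, drugs), apply_pca(pca_t, targets),
            pca_d, pca_t)


def build_balanced_dataset(drugs: FeatureTable, targets: FeatureTable,
                           interactions: InteractionSet, cfg: RunConfig,
                           seed: int) -> PairDataset:
    """Undersample negatives and assemble the labelled pair dataset
    (global PCA on all entities; use the per-fold path for CV)."""
    interactions.validate(drugs, targets)
    neg = sample_negatives(interactions, drugs.entity_ids,
                           targets.entity_ids, cfg.sampling.ratio, seed)
    dr, tr, _, _ = reduce_tables(drugs, targets, cfg)
    return build_pairs(dr, drugs.entity_ids, tr, targets.entity_ids,
                       interactions, neg.pairs)


@dataclass
class FoldResult:
    fold: int
    test_pairs: list[tuple[str, str]]
    y_true: np.ndarray
    scores: np.ndarray
    weights: tuple[float, float, float]
    base_scores: dict[str, np.ndarray]


def run_cv_repetition(drugs: FeatureTable, targets: FeatureTable,
                      interactions: InteractionSet, cfg: RunConfig,
                      scheme: str, seed: int,
                      repetition: int = 0) -> list[FoldResult]:
    """One repetition: sample negatives, deal folds, train and score."""
    from . import cascade_forest as cf
    from . import dnn as dnn_mod
    from . import grownet as gn

    neg_seed = seed if cfg.sampling.resample_negatives else \
        cfg.sampling.seed
    neg = sample_negatives(interactions, drugs.entity_ids,
                           targets.entity_ids, cfg.sampling.ratio,
                           neg_seed)
    # raw (unreduced) pair skeleton; per-fold PCA happens inside the loop
    pair_list = sorted(interactions.pairs) + sorted(neg.pairs)
    y = np.r_[np.ones(len(interactions.pairs), dtype=int),
              np.zeros(len(neg.pairs), dtype=int)]
    skeleton = PairDataset(pair_list, np.zeros((len(pair_list), 0)), y,
                           d_drug=0, d_target=0)
    fold_seed = seed if cfg.sampling.resample_folds else cfg.sampling.seed
    plan = make_cv_plan(skeleton, scheme, cfg.cv.k, fold_seed, repetition)
    results: list[FoldResult] = []
    for f, (tr_idx, te_idx) in enumerate(plan.folds):
        train_pairs = [pair_list[i] for i in tr_idx]
        train_drugs = sorted({d for d, _ in train_pairs})
        train_targets = sorted({t for _, t in train_pairs})
        if cfg.pca.per_fold:
            dr, tr_mat, _, _ = reduce_tables(
                drugs, targets, cfg,
                train_drug_ids=train_drugs,
                train_target_ids=train_targets)
        else:
            dr, tr_mat, _, _ = reduce_tables(drugs, targets, cfg)
        pos_tr = {p for p in train_pairs if p in interactions.pairs}
        neg_tr = {p for p in train_pairs if p not in interactions.pairs}
        train_ds = build_pairs(dr, drugs.entity_ids, tr_mat,
                               targets.entity_ids,
                               InteractionSet(pos_tr), neg_tr)
        test_pairs = [pair_list[i] for i in te_idx]
        d_idx = {e: i for i, e in enumerate(drugs.entity_ids)}
        t_idx = {e: i for i, e in enumerate(targets.entity_ids)}
        X_test = np.hstack([
            dr[[d_idx[d] for d, _ in test_pairs]],
            tr_mat[[t_idx[t] for _, t in test_pairs]],
        ])
        model = train_engdd(train_ds, cfg, scheme=scheme,
                            seed=int(np.random.SeedSequence(
                                (seed, repetition, f)).generate_state(1)[0]
                                % (2 ** 31)))
        base = {
            "grownet": gn.predict_grownet(model.grownet, X_test),
            "dnn": dnn_mod.predict_dnn(model.dnn, X_test),
            "cascade": cf.predict_cascade(model.cascade, X_test),
        }
        results.append(FoldResult(
            fold=f, test_pairs=test_pairs, y_true=y[te_idx],
            scores=model.predict_proba(X_test),
            weights=model.weights.as_tuple(), base_scores=base))
    return results


def evaluate_repeated(drugs: FeatureTable, targets: FeatureTable,
                      interactions: InteractionSet,
                      cfg: RunConfig | None = None,
                      scheme: str | None = None,
                      repetitions: int | None = None,
                      base_seed: int = 0) -> MetricsReport:
    """Repeated cross-validation; repetition r uses seed base_seed + r.

    Each repetition's fold-level test predictions are pooled before its
    six metrics are computed.
    """
    import pandas as pd

    cfg = cfg or RunConfig()
    scheme = scheme or cfg.cv.scheme
    repetitions = repetitions if repetitions is not None else \
        cfg.cv.repetitions
    rows = []
    for r in range(repetitions):
        folds = run_cv_repetition(drugs, targets, interactions, cfg,
                                  scheme, base_seed + r, repetition=r)
        y = np.concatenate([fr.y_true for fr in folds])
        s = np.concatenate([fr.scores for fr in folds])
        rows.append(all_metrics(y, s, cfg.ensemble.threshold))
    return MetricsReport(pd.DataFrame(rows, columns=list(METRIC_NAMES)))


def train_full(drugs: FeatureTable, targets: FeatureTable,
               interactions: InteractionSet, cfg: RunConfig | None = None,
               seed: int = 0) -> EngddModel:
    """Train one deployable model on all data (global PCA retained so
    the model can score arbitrary ID pairs later)."""
    cfg = cfg or RunConfig()
    interactions.validate(drugs, targets)
    neg = sample_negatives(interactions, drugs.entity_ids,
                           targets.entity_ids, cfg.sampling.ratio, seed)
    dr, tr, pca_d, pca_t = reduce_tables(drugs, targets, cfg)
    ds = build_pairs(dr, drugs.entity_ids, tr, targets.entity_ids,
                     interactions, neg.pairs)
    model = train_engdd(ds, cfg, scheme=cfg.cv.scheme, seed=seed)
    model.pca_drug = pca_d
    model.pca_target = pca_t
    return model
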
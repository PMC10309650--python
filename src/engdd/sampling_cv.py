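"""Negative undersampling and the three 5-fold cross-validation schemes.

Known interactions are the positives; negatives are drawn uniformly
without replacement from the unknown cells of the drug x target grid at
a 1:1 ratio by default.  Three fold schemes are supported:

* ``pair``   — plain 5-fold over pairs (both entities may be seen in
  training; the standard warm-start setting),
* ``drug``   — whole drugs held out per fold (cold-start for new drugs),
* ``target`` — whole targets held out per fold (cold-start for new
  targets).

Under the entity schemes a pair is assigned to the fold of its held-out
entity, for positives and negatives alike, so every fold sees a
consistent balanced dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .data_io import InteractionSet
from .features import PairDataset

Scheme = Literal["drug", "target", "pair"]


@dataclass
class NegativeSample:
    pairs: set[tuple[str, str]]
    seed: int
    ratio: float = 1.0


@dataclass
class CVPlan:
    """Fold assignments: folds[i] = (train pair indices, test pair indices)."""

    scheme: Scheme
    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    repetition: int = 0

    def validate(self, dataset: PairDataset) -> None:
        """Assert the partition and entity-disjointness invariants."""
        n = len(dataset)
        all_test = np.concatenate([te for _, te in self.folds])
        if len(all_test) != n or len(np.unique(all_test)) != n:
            raise AssertionError("test folds do not partition the pairs")
        for tr, te in self.folds:
            if np.intersect1d(tr, te).size:
                raise AssertionError("train/test overlap within a fold")
            if self.scheme in ("drug", "target"):
                col = 0 if self.scheme == "drug" else 1
                tr_ents = {dataset.pair_index[i][col] for i in tr}
                te_ents = {dataset.pair_index[i][col] for i in te}
                if tr_ents & te_ents:
                    raise AssertionError(
                        f"{self.scheme} IDs shared between train and test"
                    )


def sample_negatives(positives: InteractionSet, drug_ids: Sequence[str],
                     target_ids: Sequence[str], ratio: float = 1.0,
                     seed: int = 0) -> NegativeSample:
    """Uniform sample of unknown pairs, disjoint from the positives.

    ``round(ratio * n_positives)`` pairs are drawn without replacement
    from the complement of the positive set in the full grid.
    """
    n_pos = len(positives)
    n_req = int(round(ratio * n_pos))
    universe_size = len(drug_ids) * len(target_ids) - n_pos
    if universe_size < n_req:
        raise ValueError(
            f"only {universe_size} unknown pairs available, "
            f"{n_req} requested"
        )
    rng = np.random.default_rng(seed)
    n_t = len(target_ids)
    d_pos = {e: i for i, e in enumerate(drug_ids)}
    t_pos = {e: i for i, e in enumerate(target_ids)}
    pos_codes = np.fromiter(
        (d_pos[d] * n_t + t_pos[t] for d, t in positives.pairs),
        dtype=np.int64, count=n_pos,
    )
    total = len(drug_ids) * n_t
    mask = np.ones(total, dtype=bool)
    mask[pos_codes] = False
    unknown = np.flatnonzero(mask)
    chosen = rng.choice(unknown, size=n_req, replace=False)
    pairs = {(drug_ids[c // n_t], target_ids[c % n_t]) for c in chosen}
    return NegativeSample(pairs=pairs, seed=seed, ratio=ratio)


def _deal(items: np.ndarray, k: int) -> list[np.ndarray]:
    """Split shuffled items into k folds, remainders to low-index folds."""
    sizes = np.full(k, len(items) // k)
    sizes[: len(items) % k] += 1
    out, start = [], 0
    for s in sizes:
        out.append(items[start:start + s])
        start += s
    return out


def make_cv_plan(dataset: PairDataset, scheme: Scheme, k: int = 5,
                 seed: int = 0, repetition: int = 0) -> CVPlan:
    """Shuffle entities (or pairs) by seed and deal them into k folds.

    Under the ``drug``/``target`` schemes each fold's test set is exactly
    the pairs touching that fold's held-out entities.
    """
    if scheme not in ("drug", "target", "pair"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if scheme == "pair":
        if n < k:
            raise ValueError(f"{n} pairs cannot fill {k} folds")
        order = rng.permutation(n)
        test_sets = _deal(order, k)
    else:
        col = 0 if scheme == "drug" else 1
        entities = sorted({p[col] for p in dataset.pair_index})
        if len(entities) < k:
            raise ValueError(
                f"{len(entities)} distinct {scheme}s cannot fill {k} folds"
            )
        order = rng.permutation(len(entities))
        ent_folds = _deal(order, k)
        by_entity: dict[str, list[int]] = {e: [] for e in entities}
        for i, pair in enumerate(dataset.pair_index):
            by_entity[pair[col]].append(i)
        test_sets = [
            np.sort(np.concatenate(
                [np.asarray(by_entity[entities[j]], dtype=int)
                 for j in fold] or [np.empty(0, dtype=int)]
            ))
            for fold in ent_folds
        ]
    all_idx = np.arange(n)
    folds = [(np.setdiff1d(all_idx, te), np.sort(np.asarray(te, dtype=int)))
             for te in test_sets]
    plan = CVPlan(scheme=scheme, k=k, folds=folds, seed=seed,
                  repetition=repetition)
    plan.validate(dataset)
    return plan


def export_plan_tsv(plan: CVPlan, dataset: PairDataset, path) -> None:
    """Audit dump: one row per pair with its test-fold index."""
    fold_of = np.empty(len(dataset), dtype=int)
    for f, (_, te) in enumerate(plan.folds):
        fold_of[te] = f
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tlabel\ttest_fold\n")
        for i, (d, t) in enumerate(dataset.pair_index):
            fh.write(f"{d}\t{t}\t{dataset.y[i]}\t{fold_of[i]}\n")
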
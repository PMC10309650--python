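"""Dimensionality reduction and pair-vector construction.

Drug and target descriptor matrices are standardised (centred, unit
variance) and projected onto their top-``d`` principal components; a
drug-target pair is then represented by the concatenation of the two
reduced vectors.  The default ``d`` is 100 per entity type.

PCA is fit on *training* entities only within each cross-validation
round and applied to held-out entities — fitting on all entities would
leak information under the cold-start (held-out drug / held-out target)
schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .data_io import FeatureTable, InteractionSet

logger = logging.getLogger(__name__)


@dataclass
class PcaModel:
    """Frozen standardise-then-project transform.

    ``components`` has orthonormal rows (d x p); ``explained_variance``
    is non-increasing.  Each component's sign is canonicalised so its
    largest-magnitude loading is positive, making projections
    bit-reproducible across runs and BLAS builds.
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    d: int

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, scale=self.scale,
                 components=self.components,
                 explained_variance=self.explained_variance, d=self.d)

    @classmethod
    def load(cls, path) -> "PcaModel":
        z = np.load(path)
        return cls(z["mean"], z["scale"], z["components"],
                   z["explained_variance"], int(z["d"]))


@dataclass
class PairDataset:
    """Labelled drug-target pairs with concatenated reduced features.

    Row i of ``X`` is ``[reduced drug vector || reduced target vector]``
    for ``pair_index[i]``; width is ``d_drug + d_target`` (equal to
    ``2 d`` when both entity types use the same reduced dimension).
    """

    pair_index: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray
    d_drug: int
    d_target: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.pair_index) or \
                self.X.shape[0] != self.y.shape[0]:
            raise ValueError("pair_index, X and y lengths disagree")
        if self.X.shape[1] != self.d_drug + self.d_target:
            raise ValueError("X width must equal d_drug + d_target")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.pair_index)

    @property
    def drug_ids(self) -> list[str]:
        return [d for d, _ in self.pair_index]

    @property
    def target_ids(self) -> list[str]:
        return [t for _, t in self.pair_index]

    def subset(self, idx: Sequence[int]) -> "PairDataset":
        idx = np.asarray(idx, dtype=int)
        return PairDataset([self.pair_index[i] for i in idx],
                           self.X[idx], self.y[idx],
                           self.d_drug, self.d_target)


def fit_pca(table: FeatureTable, d: int, *,
            standardize: bool = True) -> PcaModel:
    """Fit a ``d``-component PCA on (optionally standardised) rows.

    Zero-variance columns get a unit scale factor with a warning.
    ``d`` must not exceed ``min(n_entities, n_features)``.
    """
    n, p = table.matrix.shape
    d_max = min(n, p)
    if not 1 <= d <= d_max:
        raise ValueError(
            f"d={d} inadmissible for a {n}x{p} table (max {d_max})"
        )
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = table.matrix.mean(axis=0)
    if standardize:
        scale = table.matrix.std(axis=0, ddof=0)
        zero = scale == 0
        if zero.any():
            logger.warning("%d zero-variance column(s); scale set to 1",
                           int(zero.sum()))
            scale = np.where(zero, 1.0, scale)
    else:
        scale = np.ones(p)
    Z = (table.matrix - mean) / scale
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(Z)
    components = pca.components_.copy()
    # canonical sign: largest-|loading| coordinate of each component positive
    for k in range(d):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] = -components[k]
    return PcaModel(mean=mean, scale=scale, components=components,
                    explained_variance=pca.explained_variance_.copy(), d=d)


def apply_pca(model: PcaModel, table: FeatureTable) -> np.ndarray:
    """Project a table through a fitted model: ((x - mean)/scale) C^T."""
    if table.n_features != model.mean.shape[0]:
        raise ValueError(
            f"table width {table.n_features} != model width "
            f"{model.mean.shape[0]}"
        )
    Z = (table.matrix - model.mean) / model.scale
    return Z @ model.components.T


def build_pairs(drug_reduced: np.ndarray, drug_ids: Sequence[str],
                target_reduced: np.ndarray, target_ids: Sequence[str],
                positives: InteractionSet,
                negatives: set[tuple[str, str]]) -> PairDataset:
    """Assemble the labelled pair dataset (drug block first).

    Positives come from the interaction set (label 1), negatives from
    the sampled unknown pairs (label 0); overlap is a hard error.
    """
    overlap = positives.pairs & negatives
    if overlap:
        raise ValueError(f"pairs both positive and negative: "
                         f"{sorted(overlap)[:5]}")
    d_idx = {e: i for i, e in enumerate(drug_ids)}
    t_idx = {e: i for i, e in enumerate(target_ids)}
    pair_list = sorted(positives.pairs) + sorted(negatives)
    y = np.r_[np.ones(len(positives.pairs), dtype=int),
              np.zeros(len(negatives), dtype=int)]
    try:
        di = np.array([d_idx[d] for d, _ in pair_list], dtype=int)
        ti = np.array([t_idx[t] for _, t in pair_list], dtype=int)
    except KeyError as exc:
        raise KeyError(f"pair references unknown entity {exc.args[0]!r}") \
            from None
    X = np.hstack([drug_reduced[di], target_reduced[ti]])
    return PairDataset(pair_list, X, y,
                       d_drug=drug_reduced.shape[1],
                       d_target=target_reduced.shape[1])
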
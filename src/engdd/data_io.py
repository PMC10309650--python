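"""Readers/writers for feature tables, interaction lists and score reports.

All on-disk formats are plain text: feature tables are TSV/CSV with a
header row and the entity ID in the first column; interaction lists are
two-column TSV edge lists (drug_id, target_id); score reports are ranked
TSV files.  ID matching is exact and case-sensitive throughout — silent
normalisation of database prefixes hides data bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Kind = Literal["drug", "target"]


class DataValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class FeatureTable:
    """ID-indexed numeric descriptor matrix for drugs or targets.

    Parameters
    ----------
    entity_ids
        Ordered, unique string identifiers (one per row of ``matrix``).
    matrix
        Dense float array of shape ``(n_entities, n_features)``.
    kind
        ``"drug"`` or ``"target"``.
    feature_names
        Optional column labels, same length as ``matrix.shape[1]``.
    """

    entity_ids: list[str]
    matrix: np.ndarray
    kind: Kind
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataValidationError("feature matrix must be 2-dimensional")
        n, p = self.matrix.shape
        if n == 0 or p == 0:
            raise DataValidationError("feature table is empty")
        if len(self.entity_ids) != n:
            raise DataValidationError(
                f"{len(self.entity_ids)} IDs for {n} matrix rows"
            )
        dupes = _duplicates(self.entity_ids)
        if dupes:
            raise DataValidationError(
                f"duplicate {self.kind} IDs: {sorted(dupes)}"
            )
        if not np.isfinite(self.matrix).all():
            bad = np.argwhere(~np.isfinite(self.matrix))[:5]
            raise DataValidationError(
                f"non-finite values at (row, col) {bad.tolist()}"
            )
        const = np.flatnonzero(np.ptp(self.matrix, axis=0) == 0)
        if const.size:
            logger.warning(
                "%s table has %d constant-valued column(s), e.g. index %d",
                self.kind, const.size, const[0],
            )

    @property
    def n_entities(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {e: i for i, e in enumerate(self.entity_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown {self.kind} ID {exc.args[0]!r}") from None

    def restrict(self, ids: Sequence[str]) -> "FeatureTable":
        """Sub-table containing only ``ids``, in the given order."""
        idx = self.index_of(ids)
        return FeatureTable(list(ids), self.matrix[idx], self.kind,
                            self.feature_names)


@dataclass
class InteractionSet:
    """Known positive drug-target pairs (implicit label 1)."""

    pairs: set[tuple[str, str]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def drug_ids(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def target_ids(self) -> set[str]:
        return {t for _, t in self.pairs}

    def validate(self, drugs: FeatureTable, targets: FeatureTable) -> None:
        unknown_d = self.drug_ids - set(drugs.entity_ids)
        unknown_t = self.target_ids - set(targets.entity_ids)
        if unknown_d or unknown_t:
            raise DataValidationError(
                f"unresolvable IDs: drugs {sorted(unknown_d)}, "
                f"targets {sorted(unknown_t)}"
            )


@dataclass
class ScoreReport:
    """Ranked interaction scores for drug-target pairs.

    Ranks are 1..n by descending score; ties are broken by lexicographic
    (drug_id, target_id) so reports are byte-identical across runs.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("drug_id", "target_id", "score", "known", "rank")

    @classmethod
    def from_scores(cls, drug_ids: Sequence[str], target_ids: Sequence[str],
                    scores: Sequence[float],
                    known: Sequence[bool]) -> "ScoreReport":
        df = pd.DataFrame({
            "drug_id": list(drug_ids),
            "target_id": list(target_ids),
            "score": np.asarray(scores, dtype=float),
            "known": np.asarray(known, dtype=bool),
        })
        if ((df["score"] < 0) | (df["score"] > 1)).any():
            raise DataValidationError("scores must lie in [0, 1]")
        df = df.sort_values(
            by=["score", "drug_id", "target_id"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return cls(df)

    def head(self, top_k: int | None) -> pd.DataFrame:
        return self.frame if top_k is None else self.frame.head(top_k)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_feature_table(path: str | Path, kind: Kind,
                       sep: str | None = None) -> FeatureTable:
    """Load a descriptor table (header row, first column = entity ID).

    The delimiter is sniffed from the header line unless ``sep`` is given.
    Rows with any non-numeric cell and duplicated IDs are hard errors:
    missing values are rejected rather than imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise DataValidationError(f"{path}: empty or ID-only table")
    ids = df.iloc[:, 0].tolist()
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric cell at row {ids[r]!r}, "
            f"column {values.columns[c]!r}"
        )
    return FeatureTable(ids, values.to_numpy(dtype=float), kind,
                        feature_names=list(values.columns))


def write_feature_table(table: FeatureTable, path: str | Path,
                        sep: str = "\t") -> None:
    names = table.feature_names or [f"f{i}" for i in range(table.n_features)]
    df = pd.DataFrame(table.matrix, columns=names)
    df.insert(0, "id", table.entity_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_interactions(path: str | Path, drugs: FeatureTable,
                      targets: FeatureTable, *,
                      permissive: bool = False) -> InteractionSet:
    """Load a two-column (drug_id, target_id) edge list.

    Every ID must resolve against the feature tables; with
    ``permissive=True`` unresolvable pairs are skipped with a logged count
    instead of raising.  Duplicate pairs are collapsed and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), header=None, dtype=str,
                     comment="#")
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected two columns")
    # tolerate a header line naming the columns
    if df.iloc[0, 0].lower() in {"drug_id", "drug", "id"}:
        df = df.iloc[1:]
    raw = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    pairs = set(raw)
    if len(pairs) < len(raw):
        logger.info("collapsed %d duplicate pair(s)", len(raw) - len(pairs))
    known_d, known_t = set(drugs.entity_ids), set(targets.entity_ids)
    bad = {p for p in pairs if p[0] not in known_d or p[1] not in known_t}
    if bad:
        if not permissive:
            raise DataValidationError(
                f"{path}: unresolvable pair IDs, e.g. {sorted(bad)[:5]}"
            )
        logger.warning("skipping %d pair(s) with unknown IDs", len(bad))
        pairs -= bad
    return InteractionSet(pairs, provenance=str(path))


def write_interactions(interactions: InteractionSet,
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, t in sorted(interactions.pairs):
            fh.write(f"{d}\t{t}\n")


def write_score_report(report: ScoreReport, path: str | Path,
                       top_k: int | None = None) -> None:
    """Write a ranked TSV (drug_id, target_id, score, known, rank).

    Scores are printed with 6 decimal places; rows appear in rank order,
    truncated to ``top_k`` when given.  Known pairs carry ``known=true``
    so newly predicted candidates are distinguishable.
    """
    df = report.head(top_k).copy()
    df["score"] = df["score"].map(lambda s: f"{s:.6f}")
    df["known"] = df["known"].map(lambda k: "true" if k else "false")
    df.to_csv(path, sep="\t", index=False)


def read_score_report(path: str | Path) -> ScoreReport:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    df["known"] = df["known"].astype(str).str.lower() == "true"
    return ScoreReport(df[list(ScoreReport.COLUMNS)])
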
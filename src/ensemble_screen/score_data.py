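"""Data model and I/O for docking-score matrices and ligand class labels.

The central exchange object is :class:`ScoreMatrix`: a ligands x receptor-
conformations grid of docking scores (lower = more favourable, the Glide
convention) together with a boolean *failed* grid marking ligand/conformation
pairs for which the docking engine returned no pose.  Failure is an explicit
flag, never a sentinel score, so a legitimate score of 0.0 cannot collide
with "could not be docked".

CSV layout
----------
Score matrix: header ``ligand_id,<conf1>,<conf2>,...``; one row per ligand;
cells are decimal numbers or a failure token (``NA``, ``N/A`` or empty).
Labels: header ``ligand_id,class`` with class in {agonist, antagonist, decoy}.
Unicode minus signs (U+2212), as printed in typesetting, are normalised to
ASCII ``-`` on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ensemble_screen")

#: The three ligand classes the package recognises.
LIGAND_CLASSES = ("agonist", "antagonist", "decoy")

#: Tokens accepted as "docking failed" when reading a score CSV.
FAILURE_TOKENS = ("NA", "N/A", "")

_UNICODE_MINUS = "−"


class ScoreDataError(ValueError):
    """Raised for malformed score matrices or label tables."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Docking scores for ``n_ligands x n_conformations`` pairs.

    Parameters
    ----------
    ligand_ids, conformation_ids
        Ordered, unique identifiers for the two axes.
    scores
        Float grid in docking-score units; lower means higher predicted
        affinity.  Entries where ``failed`` is True are undefined (stored as
        NaN) and ignored by every downstream operation.
    failed
        Boolean grid of the same shape; True marks a docking failure.
    """

    ligand_ids: tuple[str, ...]
    conformation_ids: tuple[str, ...]
    scores: np.ndarray
    failed: np.ndarray

    def __post_init__(self) -> None:
        lig = tuple(str(x) for x in self.ligand_ids)
        conf = tuple(str(x) for x in self.conformation_ids)
        object.__setattr__(self, "ligand_ids", lig)
        object.__setattr__(self, "conformation_ids", conf)
        if len(set(lig)) != len(lig):
            raise ScoreDataError("duplicate ligand ids")
        if len(set(conf)) != len(conf):
            raise ScoreDataError("duplicate conformation ids")
        scores = np.asarray(self.scores, dtype=float)
        failed = np.asarray(self.failed, dtype=bool)
        if scores.shape != (len(lig), len(conf)):
            raise ScoreDataError(
                f"scores shape {scores.shape} != ({len(lig)}, {len(conf)})"
            )
        if failed.shape != scores.shape:
            raise ScoreDataError("failed grid shape differs from scores")
        if not np.all(np.isfinite(scores[~failed])):
            raise ScoreDataError("non-finite score in a non-failed cell")
        scores = scores.copy()
        scores[failed] = np.nan  # failed cells carry no score
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "failed", failed.copy())

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_conformations(self) -> int:
        return len(self.conformation_ids)

    def ligand_index(self, ligand_id: str) -> int:
        return self.ligand_ids.index(ligand_id)

    def conformation_indices(self, members) -> np.ndarray:
        """Column indices of ``members``, erroring on unknown ids."""
        idx = []
        for m in members:
            if m not in self.conformation_ids:
                raise ScoreDataError(f"unknown conformation id: {m!r}")
            idx.append(self.conformation_ids.index(m))
        return np.asarray(idx, dtype=int)

    def subset_ligands(self, ligand_ids) -> "ScoreMatrix":
        rows = [self.ligand_index(l) for l in ligand_ids]
        return ScoreMatrix(
            tuple(ligand_ids),
            self.conformation_ids,
            self.scores[rows],
            self.failed[rows],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreMatrix):
            return NotImplemented
        return (
            self.ligand_ids == other.ligand_ids
            and self.conformation_ids == other.conformation_ids
            and np.array_equal(self.failed, other.failed)
            and np.allclose(
                self.scores[~self.failed], other.scores[~other.failed]
            )
        )


@dataclass(frozen=True)
class LigandLabels:
    """Mapping ligand id -> class in {agonist, antagonist, decoy}."""

    classes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for lig, cls in dict(self.classes).items():
            if cls not in LIGAND_CLASSES:
                raise ScoreDataError(
                    f"unknown class {cls!r} for ligand {lig!r}; "
                    f"expected one of {LIGAND_CLASSES}"
                )
            clean[str(lig)] = cls
        object.__setattr__(self, "classes", clean)

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, ligand_id: str) -> str:
        return self.classes[ligand_id]

    def __contains__(self, ligand_id: str) -> bool:
        return ligand_id in self.classes

    def ids_of(self, cls: str) -> list[str]:
        if cls not in LIGAND_CLASSES:
            raise ScoreDataError(f"unknown class {cls!r}")
        return [l for l, c in self.classes.items() if c == cls]


def _clean_cell(value: object) -> str:
    s = str(value).strip().replace(_UNICODE_MINUS, "-")
    return s


def load_score_matrix(path: str | Path, *, delimiter: str = ",") -> ScoreMatrix:
    """Read a score-matrix CSV into a validated :class:`ScoreMatrix`.

    Failure tokens (``NA``, ``N/A``, empty cell) become ``failed=True``.
    Duplicate ids or non-numeric cells raise :class:`ScoreDataError` naming
    the offending row/column.
    """
    path = Path(path)
    df = pd.read_csv(
        path, delimiter=delimiter, dtype=str, keep_default_na=False, index_col=0
    )
    ligand_ids = [_clean_cell(x) for x in df.index]
    conf_ids = [_clean_cell(x) for x in df.columns]
    if len(set(ligand_ids)) != len(ligand_ids):
        raise ScoreDataError(f"{path.name}: duplicate ligand id in first column")
    if len(set(conf_ids)) != len(conf_ids):
        raise ScoreDataError(f"{path.name}: duplicate conformation id in header")
    scores = np.full((len(ligand_ids), len(conf_ids)), np.nan)
    failed = np.zeros_like(scores, dtype=bool)
    for i, lig in enumerate(ligand_ids):
        for j, conf in enumerate(conf_ids):
            raw = _clean_cell(df.iat[i, j])
            if raw.upper() in ("NA", "N/A") or raw == "":
                failed[i, j] = True
                continue
            try:
                scores[i, j] = float(raw)
            except ValueError as exc:
                raise ScoreDataError(
                    f"{path.name}: non-numeric cell {raw!r} at "
                    f"ligand {lig!r}, conformation {conf!r}"
                ) from exc
    return ScoreMatrix(tuple(ligand_ids), tuple(conf_ids), scores, failed)


def save_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write a ScoreMatrix as CSV, encoding failed cells as ``NA``."""
    cells = np.empty(matrix.scores.shape, dtype=object)
    for i in range(matrix.n_ligands):
        for j in range(matrix.n_conformations):
            cells[i, j] = (
                "NA" if matrix.failed[i, j] else repr(float(matrix.scores[i, j]))
            )
    df = pd.DataFrame(
        cells, index=list(matrix.ligand_ids), columns=list(matrix.conformation_ids)
    )
    df.index.name = "ligand_id"
    df.to_csv(path)


def load_labels(path: str | Path) -> LigandLabels:
    """Read a two-column ``ligand_id,class`` CSV into :class:`LigandLabels`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ScoreDataError(f"{path.name}: expected two columns (ligand_id,class)")
    mapping: dict[str, str] = {}
    for lig, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        lig = _clean_cell(lig)
        cls = _clean_cell(cls).lower()
        if lig in mapping:
            raise ScoreDataError(f"{path.name}: duplicate ligand id {lig!r}")
        mapping[lig] = cls
    return LigandLabels(mapping)


def save_labels(labels: LigandLabels, path: str | Path) -> None:
    df = pd.DataFrame(
        {"ligand_id": list(labels.classes), "class": list(labels.classes.values())}
    )
    df.to_csv(path, index=False)


def align(
    matrix: ScoreMatrix, labels: LigandLabels
) -> tuple[ScoreMatrix, LigandLabels]:
    """Restrict both objects to their common ligand ids (matrix order kept).

    Ids present on only one side are dropped with a logged warning; an empty
    intersection is an error.
    """
    common = [l for l in matrix.ligand_ids if l in labels]
    if not common:
        raise ScoreDataError("no ligand ids shared between matrix and labels")
    dropped_m = [l for l in matrix.ligand_ids if l not in labels]
    dropped_l = [l for l in labels.classes if l not in matrix.ligand_ids]
    if dropped_m:
        logger.warning("align: dropped %d unlabelled matrix ligands", len(dropped_m))
    if dropped_l:
        logger.warning("align: dropped %d labels absent from matrix", len(dropped_l))
    if not dropped_m and not dropped_l:
        return matrix, labels
    sub_matrix = matrix.subset_ligands(common)
    sub_labels = LigandLabels({l: labels[l] for l in common})
    return sub_matrix, sub_labels
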
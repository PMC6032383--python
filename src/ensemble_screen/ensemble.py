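"""Ensemble-score aggregation, objective evaluation and exhaustive subset
search.

In ensemble docking a ligand is docked against several rigid receptor
conformations and its final score is the best (minimum) score across the
ensemble members; a ligand counts as failed only if it failed on every
member.  An ensemble of size ``k`` is then judged by the enrichment it
yields — the ROC AUC of one ligand class against the decoys, or the sum of
two AUC terms when selectivity against a second class matters — and the
best size-``k`` ensemble out of a pool of ``n`` conformations is found by
evaluating all C(n, k) subsets.

At the pool sizes conformational ensembles come in (a dozen MD cluster
representatives, C(12,5) = 792 candidates) exhaustive search is cheap and,
unlike greedy selection, guaranteed optimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from .metrics import RocResult, roc_auc
from .score_data import LIGAND_CLASSES, LigandLabels, ScoreDataError, ScoreMatrix

OBJECTIVE_KINDS = ("auc_vs_decoys", "summed_auc")


@dataclass(frozen=True)
class Objective:
    """Selection objective for the ensemble search.

    ``auc_vs_decoys`` maximises AUC(active_class vs decoys).  ``summed_auc``
    maximises AUC(active_class vs decoys) + AUC(active_class vs other_class),
    both terms weighted equally.
    """

    kind: str
    active_class: str
    other_class: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.active_class not in LIGAND_CLASSES:
            raise ValueError(f"unknown class {self.active_class!r}")
        if self.kind == "summed_auc":
            if self.other_class is None:
                raise ValueError("summed_auc requires other_class")
            if self.other_class not in LIGAND_CLASSES:
                raise ValueError(f"unknown class {self.other_class!r}")
            if self.other_class == self.active_class:
                raise ValueError("active_class and other_class must differ")

    def describe(self) -> str:
        if self.kind == "auc_vs_decoys":
            return f"AUC({self.active_class} vs decoy)"
        return (
            f"AUC({self.active_class} vs decoy) + "
            f"AUC({self.active_class} vs {self.other_class})"
        )


@dataclass(frozen=True)
class EnsembleResult:
    """A member subset with its aggregated scores and objective value(s)."""

    members: tuple[str, ...]
    aggregated: np.ndarray  # per-ligand best score; NaN = failed on all members
    objective_values: tuple[float, ...]
    objective_total: float
    roc_results: tuple[RocResult, ...] = ()

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("ensemble must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate ensemble members")
        if not np.isclose(self.objective_total, sum(self.objective_values)):
            raise ValueError("objective_total != sum(objective_values)")


def aggregate_scores(matrix: ScoreMatrix, members) -> np.ndarray:
    """Best-across-ensemble score per ligand.

    Returns a float vector aligned with ``matrix.ligand_ids``: the minimum
    score over the non-failed cells of the member columns, or NaN where the
    ligand failed on every member.
    """
    members = list(members)
    if not members:
        raise ScoreDataError("members must be non-empty")
    cols = matrix.conformation_indices(members)
    sub = matrix.scores[:, cols].copy()
    sub[matrix.failed[:, cols]] = np.inf
    best = sub.min(axis=1)
    best[np.isinf(best)] = np.nan
    return best


def _class_rows(matrix: ScoreMatrix, labels: LigandLabels) -> dict[str, np.ndarray]:
    rows: dict[str, list[int]] = {c: [] for c in LIGAND_CLASSES}
    for i, lig in enumerate(matrix.ligand_ids):
        if lig in labels:
            rows[labels[lig]].append(i)
    return {c: np.asarray(r, dtype=int) for c, r in rows.items()}


def _objective_terms(objective: Objective) -> list[tuple[str, str]]:
    terms = [(objective.active_class, "decoy")]
    if objective.kind == "summed_auc":
        terms.append((objective.active_class, objective.other_class))
    return terms


def evaluate_ensemble(
    matrix: ScoreMatrix,
    labels: LigandLabels,
    members,
    objective: Objective,
) -> EnsembleResult:
    """Aggregate over ``members`` and score the ensemble under ``objective``.

    Members are reported in sorted id order (the canonical form used for
    tie-breaking in the search).
    """
    members = tuple(sorted(members))
    agg = aggregate_scores(matrix, members)
    class_rows = _class_rows(matrix, labels)
    values: list[float] = []
    rocs: list[RocResult] = []
    for active_cls, inactive_cls in _objective_terms(objective):
        for cls in (active_cls, inactive_cls):
            if class_rows[cls].size == 0:
                raise ScoreDataError(f"objective requires ligands of class {cls!r}")
        res = roc_auc(agg[class_rows[active_cls]], agg[class_rows[inactive_cls]])
        values.append(res.auc)
        rocs.append(res)
    return EnsembleResult(
        members=members,
        aggregated=agg,
        objective_values=tuple(values),
        objective_total=float(sum(values)),
        roc_results=tuple(rocs),
    )


def _auc_columns(agg: np.ndarray, active_rows: np.ndarray, inactive_rows: np.ndarray) -> np.ndarray:
    """Vectorised AUC over the columns of an aggregated-score matrix.

    ``agg`` is (n_ligands, n_candidates) with NaN = failed; the return value
    matches :func:`ensemble_screen.metrics.roc_auc` column by column.
    """
    sub = agg[np.concatenate([active_rows, inactive_rows]), :].copy()
    sub[np.isnan(sub)] = np.inf
    ranks = rankdata(sub, method="average", axis=0)
    n_a, n_i = active_rows.size, inactive_rows.size
    u_worse = ranks[:n_a, :].sum(axis=0) - n_a * (n_a + 1) / 2.0
    return (n_a * n_i - u_worse) / (n_a * n_i)


def exhaustive_search(
    matrix: ScoreMatrix,
    labels: LigandLabels,
    k: int,
    objective: Objective,
) -> tuple[EnsembleResult, list[EnsembleResult]]:
    """Evaluate every size-``k`` conformation subset; return the best and all.

    Ties on the objective total are broken by the lexicographically smallest
    member-id tuple, so the winner is deterministic.  The full candidate
    list, sorted by descending objective, is returned alongside for
    secondary selections (e.g. re-ranking the same pool under a different
    report).
    """
    n = matrix.n_conformations
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    class_rows = _class_rows(matrix, labels)
    terms = _objective_terms(objective)
    for active_cls, inactive_cls in terms:
        for cls in (active_cls, inactive_cls):
            if class_rows[cls].size == 0:
                raise ScoreDataError(f"objective requires ligands of class {cls!r}")

    subsets = list(combinations(range(n), k))
    masked = matrix.scores.copy()
    masked[matrix.failed] = np.inf
    agg = np.empty((matrix.n_ligands, len(subsets)))
    for j, idx in enumerate(subsets):
        agg[:, j] = masked[:, list(idx)].min(axis=1)
    agg[np.isinf(agg)] = np.nan

    per_term = [
        _auc_columns(agg, class_rows[a], class_rows[b]) for a, b in terms
    ]
    totals = np.sum(per_term, axis=0)

    results = [
        EnsembleResult(
            members=tuple(sorted(matrix.conformation_ids[i] for i in idx)),
            aggregated=agg[:, j],
            objective_values=tuple(float(t[j]) for t in per_term),
            objective_total=float(totals[j]),
        )
        for j, idx in enumerate(subsets)
    ]
    results.sort(key=lambda r: (-r.objective_total, r.members))
    return results[0], results
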
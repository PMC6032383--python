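"""Virtual-screening enrichment statistics.

ROC AUC is the probability that a randomly chosen active is ranked better
(more negative docking score) than a randomly chosen inactive.  It is
computed through the Mann-Whitney rank formulation with midrank tie
handling, which makes the antisymmetry identity
``auc(A, B) + auc(B, A) == 1`` hold exactly.

Docking failures are censored to the shared worst rank: a ligand the engine
could not dock must not outrank any ligand with a finite score, and two
failed ligands are mutually tied (each such pair contributes 1/2).
Internally a failure is encoded as ``+inf`` before ranking, which realises
exactly that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .score_data import LIGAND_CLASSES, LigandLabels, ScoreDataError, ScoreMatrix


@dataclass(frozen=True)
class RocResult:
    """ROC AUC plus the group sizes and failure counts behind it."""

    auc: float
    n_actives: int
    n_inactives: int
    n_failed_actives: int
    n_failed_inactives: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")
        if self.n_failed_actives > self.n_actives:
            raise ValueError("more failed actives than actives")
        if self.n_failed_inactives > self.n_inactives:
            raise ValueError("more failed inactives than inactives")


def _censor(scores) -> np.ndarray:
    """Float vector with failures (None/NaN) mapped to +inf (worst rank)."""
    arr = np.array(
        [np.nan if s is None else float(s) for s in np.ravel(np.asarray(scores, dtype=object))],
        dtype=float,
    )
    arr[np.isnan(arr)] = np.inf
    return arr


def roc_auc(active_scores, inactive_scores) -> RocResult:
    """ROC AUC of actives vs inactives under lower-is-better scoring.

    Parameters
    ----------
    active_scores, inactive_scores
        Sequences of docking scores; ``None``/NaN marks a docking failure.

    Returns
    -------
    RocResult
        ``auc`` equals the brute-force pairwise statistic
        ``mean(win=1, tie=1/2, loss=0)`` over all active/inactive pairs.
    """
    a = _censor(active_scores)
    b = _censor(inactive_scores)
    if a.size == 0 or b.size == 0:
        raise ValueError("roc_auc requires at least one active and one inactive")
    ranks = rankdata(np.concatenate([a, b]), method="average")
    # wins = (active better than inactive) pairs, ties as 1/2; the half-
    # integer count is exact in floating point, so a single division keeps
    # auc(A,B) + auc(B,A) == 1 bit-exact.
    u_worse = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    wins = a.size * b.size - u_worse
    auc = wins / (a.size * b.size)
    return RocResult(
        auc=float(auc),
        n_actives=int(a.size),
        n_inactives=int(b.size),
        n_failed_actives=int(np.isinf(a).sum()),
        n_failed_inactives=int(np.isinf(b).sum()),
    )


@dataclass(frozen=True)
class ClassDistribution:
    """Histogram summary of ensemble-aggregated scores for one ligand class."""

    ligand_class: str
    bin_edges: np.ndarray  # len n_bins + 1; empty if no finite scores
    counts: np.ndarray  # len n_bins
    n_total: int
    n_failed: int
    threshold: float
    fraction_at_or_below: float  # fraction of ALL class ligands <= threshold

    @property
    def fraction_failed(self) -> float:
        return self.n_failed / self.n_total if self.n_total else 0.0


def score_distribution(
    matrix: ScoreMatrix,
    labels: LigandLabels,
    members,
    *,
    threshold: float = -10.0,
    bin_width: float = 1.0,
) -> dict[str, ClassDistribution]:
    """Per-class histograms of best-across-ensemble docking scores.

    Each ligand's score is its minimum over the non-failed cells of the
    member conformations; ligands failing on every member are tallied in a
    separate failed bin and excluded from the score histogram.  The
    ``fraction_at_or_below`` uses all ligands of the class as denominator
    (a failed ligand cannot reach the threshold), matching how screening
    studies quote "x% of actives reached a score of -10.0 or lower".
    """
    from .ensemble import aggregate_scores  # local import: no module cycle at load

    members = list(members)
    if not members:
        raise ValueError("members must be a non-empty subset of conformations")
    agg = aggregate_scores(matrix, members)  # NaN = failed on all members
    out: dict[str, ClassDistribution] = {}
    finite_all = agg[np.isfinite(agg)]
    if finite_all.size:
        lo = np.floor(finite_all.min() / bin_width) * bin_width
        hi = np.ceil(finite_all.max() / bin_width) * bin_width
        hi = hi if hi > lo else lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
    else:
        edges = np.array([])
    for cls in LIGAND_CLASSES:
        rows = [i for i, l in enumerate(matrix.ligand_ids) if l in labels and labels[l] == cls]
        if not rows:
            continue
        vals = agg[rows]
        finite = vals[np.isfinite(vals)]
        counts = (
            np.histogram(finite, bins=edges)[0] if edges.size else np.array([], dtype=int)
        )
        out[cls] = ClassDistribution(
            ligand_class=cls,
            bin_edges=edges,
            counts=counts,
            n_total=len(rows),
            n_failed=int(np.isnan(vals).sum()),
            threshold=threshold,
            fraction_at_or_below=float((finite <= threshold).sum() / len(rows)),
        )
    return out


def distribution_table(dists: dict[str, ClassDistribution]):
    """Flatten histogram summaries to rows (class, bin_low, bin_high, count)."""
    import pandas as pd

    rows = []
    for cls, d in dists.items():
        for k in range(len(d.counts)):
            rows.append(
                {
                    "class": cls,
                    "bin_low": d.bin_edges[k],
                    "bin_high": d.bin_edges[k + 1],
                    "count": int(d.counts[k]),
                }
            )
        rows.append(
            {"class": cls, "bin_low": np.nan, "bin_high": np.nan, "count": d.n_failed}
        )
    return pd.DataFrame(rows, columns=["class", "bin_low", "bin_high", "count"])
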
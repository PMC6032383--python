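"""End-to-end orchestration: cross-docking reports and the full benchmark.

``run_crossdock_report`` reproduces the classic sanity check on a
cross-docking grid: does every ligand obtain its best score against the
receptor conformation it was crystallised with?  ``run_full_benchmark``
drives the whole workflow — score matrix in (real CSVs or the synthetic
generator), exhaustive ensemble selection under the single and summed
objectives for both active classes, cross-evaluation of every selected
ensemble against every ligand class, and a report table with one row per
(ensemble, actives, decoys) combination.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, score_data, synthetic
from .ensemble import EnsembleResult, Objective, aggregate_scores, exhaustive_search
from .score_data import LigandLabels, ScoreDataError, ScoreMatrix

logger = logging.getLogger("ensemble_screen")


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass(frozen=True)
class CrossdockRow:
    ligand_id: str
    best_conformation: str | None  # None if the ligand failed everywhere
    best_score: float | None
    native_conformation: str
    native_best: bool
    n_failed: int


@dataclass(frozen=True)
class CrossdockReport:
    rows: tuple[CrossdockRow, ...]
    n_native_best: int
    n_failed_cells: int

    def summary(self) -> str:
        return (
            f"{self.n_native_best}/{len(self.rows)} ligands best on their "
            f"native conformation; {self.n_failed_cells} failed cells"
        )


def run_crossdock_report(
    matrix: ScoreMatrix, native_map: dict[str, str]
) -> CrossdockReport:
    """Per-ligand best conformation vs its native conformation.

    ``native_map`` maps ligand id -> the conformation id it originates from.
    Ties on the best score resolve to the first conformation in matrix
    column order.
    """
    for lig, conf in native_map.items():
        if conf not in matrix.conformation_ids:
            raise ScoreDataError(f"native conformation {conf!r} not in matrix")
    rows = []
    n_native_best = 0
    for i, lig in enumerate(matrix.ligand_ids):
        if lig not in native_map:
            raise ScoreDataError(f"no native conformation mapped for ligand {lig!r}")
        scores = matrix.scores[i].copy()
        scores[matrix.failed[i]] = np.inf
        j = int(np.argmin(scores))
        all_failed = bool(np.isinf(scores[j]))
        best_conf = None if all_failed else matrix.conformation_ids[j]
        native_best = best_conf == native_map[lig]
        n_native_best += int(native_best)
        rows.append(
            CrossdockRow(
                ligand_id=lig,
                best_conformation=best_conf,
                best_score=None if all_failed else float(scores[j]),
                native_conformation=native_map[lig],
                native_best=native_best,
                n_failed=int(matrix.failed[i].sum()),
            )
        )
    return CrossdockReport(
        tuple(rows), n_native_best, int(matrix.failed.sum())
    )


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full benchmark run.

    Either ``scores_path``+``labels_path`` point at CSV inputs, or
    ``simulate`` holds a :class:`~ensemble_screen.synthetic.ScoreGenConfig`
    used to generate them.  All thresholds of the workflow are surfaced
    here: ensemble size ``k`` (default 5), the score threshold quoted in
    distribution summaries (default -10.0), and the seed.
    """

    scores_path: str | None = None
    labels_path: str | None = None
    simulate: synthetic.ScoreGenConfig | None = None
    k: int = 5
    threshold: float = -10.0
    seed: int = 0
    out_dir: str | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        sim_cfg = synthetic.ScoreGenConfig(**sim) if sim is not None else None
        return RunConfig(simulate=sim_cfg, **raw)


@dataclass(frozen=True)
class BenchmarkReport:
    """Selected ensembles plus the cross-evaluation table."""

    ensembles: dict[str, EnsembleResult]
    table: pd.DataFrame  # columns: ensemble, auc, actives, decoys
    matrix: ScoreMatrix = field(repr=False, default=None)
    labels: LigandLabels = field(repr=False, default=None)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_full_benchmark(config: RunConfig) -> BenchmarkReport:
    """Select best ensembles under every objective and cross-evaluate them.

    Selections mirror the standard benchmark design: for each active class
    (antagonist, agonist) the best size-k ensemble against the decoys
    (single objective) and the best ensemble under the summed objective
    (class vs decoys plus class vs the other active class).  Every selected
    ensemble is then evaluated against all (actives, decoys) pairs and the
    results are collected into one table row per combination.
    """
    if config.simulate is not None:
        matrix, labels, _ = _stage("simulate")(
            synthetic.gen_score_matrix, config.simulate.with_seed(config.seed)
        )
    else:
        if config.scores_path is None or config.labels_path is None:
            raise PipelineError("stage 'load': need scores_path and labels_path or a simulate block")
        matrix = _stage("load_scores")(score_data.load_score_matrix, config.scores_path)
        labels = _stage("load_labels")(score_data.load_labels, config.labels_path)
    matrix, labels = _stage("align")(score_data.align, matrix, labels)
    logger.info(
        "benchmark input: %d ligands x %d conformations", matrix.n_ligands, matrix.n_conformations
    )

    selections = {
        "antagonist_best": Objective("auc_vs_decoys", "antagonist"),
        "agonist_best": Objective("auc_vs_decoys", "agonist"),
        "antagonist_summed": Objective("summed_auc", "antagonist", "agonist"),
        "agonist_summed": Objective("summed_auc", "agonist", "antagonist"),
    }
    ensembles: dict[str, EnsembleResult] = {}
    for name, objective in selections.items():
        best, _ = _stage(f"search_{name}")(
            exhaustive_search, matrix, labels, config.k, objective
        )
        ensembles[name] = best
        logger.info(
            "%s: members=%s total=%.3f", name, ",".join(best.members), best.objective_total
        )

    class_rows = {
        cls: [i for i, l in enumerate(matrix.ligand_ids) if labels[l] == cls]
        for cls in score_data.LIGAND_CLASSES
    }
    table_rows = []
    for name, res in ensembles.items():
        agg = res.aggregated
        for actives, inactives in (
            ("agonist", "decoy"),
            ("antagonist", "decoy"),
            ("agonist", "antagonist"),
            ("antagonist", "agonist"),
        ):
            if not class_rows[actives] or not class_rows[inactives]:
                continue
            r = metrics.roc_auc(agg[class_rows[actives]], agg[class_rows[inactives]])
            table_rows.append(
                {"ensemble": name, "auc": r.auc, "actives": actives, "decoys": inactives}
            )
    table = pd.DataFrame(table_rows, columns=["ensemble", "auc", "actives", "decoys"])

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "benchmark_table.csv", index=False)
        payload = {
            name: {
                "members": list(res.members),
                "objective_values": list(res.objective_values),
                "objective_total": res.objective_total,
            }
            for name, res in ensembles.items()
        }
        (out / "ensembles.json").write_text(json.dumps(payload, indent=2))
        for name, res in ensembles.items():
            dists = metrics.score_distribution(
                matrix, labels, res.members, threshold=config.threshold
            )
            metrics.distribution_table(dists).to_csv(
                out / f"distribution_{name}.csv", index=False
            )
    return BenchmarkReport(ensembles=ensembles, table=table, matrix=matrix, labels=labels)
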
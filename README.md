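# ensemble-screen

Analysis toolkit for **ensemble docking** in structure-based virtual
screening, built around the androgen-receptor (AR) use case: a nuclear
receptor with no experimental antagonist-bound structure, where docking
against agonist crystal structures is biased against antagonists, and
receptor conformations generated by molecular dynamics must be selected to
recover antagonist enrichment.

The package is aimed at computational chemists who already have per-ligand
docking scores against a pool of receptor conformations (e.g. Glide SP
scores against MD cluster representatives) and need the downstream
analysis: score aggregation, enrichment metrics, optimal ensemble
selection, and the structure-side clustering that produces the
conformation pool in the first place.

## What it computes

**Ensemble aggregation.** For an ensemble *E* of receptor conformations, a
ligand's final docking score is its best score across the members
(lower = better, the Glide convention):

    s(l, E) = min_{c in E, not failed(l, c)} s(l, c)

A ligand counts as failed only if the engine produced no pose for any
member. Failure is an explicit flag, never a sentinel score.

**Enrichment.** ROC AUC via the Mann–Whitney rank statistic with midrank
ties: the probability that a randomly chosen active outranks a randomly
chosen inactive, with docking failures censored to the shared worst rank.
The single-division formulation keeps `auc(A,B) + auc(B,A) = 1` bit-exact.

**Ensemble selection.** Exhaustive search over all C(n, k) size-*k*
subsets of the conformation pool (default k = 5), maximising either
AUC(actives vs decoys) or the summed objective
AUC(actives vs decoys) + AUC(actives vs other-class). At realistic pool
sizes (C(12,5) = 792) this is fast and guaranteed optimal.

**Structure machinery.** Multi-MODEL PDB ingestion (biotite), binding-site
selection by a 5.0 Å heavy-atom cutoff around the bound ligand, Kabsch-
superposed heavy-atom RMSD, affinity-propagation clustering of trajectory
frames on the binding-site RMSD matrix (exemplars of the three most
populated clusters become the representative structures), average-linkage
clustering of crystal structures by binding-site similarity, and a
grid/flood-fill pocket-volume estimate.

**Synthetic benchmark.** A generator of score matrices with planted
class/conformation structure (promiscuous agonists, conformation-selective
antagonists, class-dependent docking failures, 118/115/3000
agonist/antagonist/decoy set sizes) and of toy multi-frame coordinate sets
with planted conformational clusters, so the whole pipeline is testable
without a docking engine.

## Worked example

The package bundles a published 5×5 cross-docking grid: the co-crystallised
ligands of five AR structures (3B66, 3G0W, 3V49, 4HLW, 2PNU) docked into
all five receptor conformations.

```python
import ensemble_screen as es

matrix, labels, native = es.load_crossdock_example()
agg = es.aggregate_scores(matrix, matrix.conformation_ids)
print(dict(zip(matrix.ligand_ids, agg)))
report = es.run_crossdock_report(matrix, native)
print(report.summary())
```

prints

```
{'3B66': -12.2, '3G0W': -11.2, '3V49': -12.2, '4HLW': -11.3, '2PNU': -14.2}
5/5 ligands best on their native conformation; 8 failed cells
```

Every ligand's best-across-ensemble score is attained at its native
structure — the classic cross-docking sanity check — and 8 of the 25
ligand/structure pairs could not be docked at all (the bulky 2PNU ligand
fits only its own induced-fit pocket).

The same workflow at benchmark scale, from the synthetic generator:

```sh
ensemble-screen simulate --seed 17 --out-prefix run1
ensemble-screen select --scores run1_scores.csv --labels run1_labels.csv \
    --k 5 --objective auc_vs_decoys --active-class antagonist
```

which reports the optimal ensemble members (antagonist-friendly
conformations are recovered from the pool) with their AUC. A full
`benchmark` subcommand runs all selections and cross-evaluations from a
YAML config and writes a report table with one row per
(ensemble, actives, decoys) combination.

## Layout

- `src/ensemble_screen/score_data.py` — score-matrix / label model and CSV I/O
- `src/ensemble_screen/metrics.py` — ROC AUC with failure censoring, score distributions
- `src/ensemble_screen/ensemble.py` — aggregation, objectives, exhaustive search
- `src/ensemble_screen/struct_cluster.py` — frames, RMSD, affinity propagation, pocket volume
- `src/ensemble_screen/synthetic.py` — planted-structure generators
- `src/ensemble_screen/pipeline.py`, `cli.py` — orchestration and the `ensemble-screen` CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
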
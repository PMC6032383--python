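"""Synthetic score matrices and toy coordinate sets with planted structure.

These generators stand in for the docking engine and the MD engine so that
every downstream stage (aggregation, enrichment, ensemble search,
clustering) can be exercised and validated against known ground truth.

The score generator draws each ligand x conformation cell from a Gaussian
whose mean and spread depend on the ligand class (agonist / antagonist /
decoy) and the conformation type (agonist-like / antagonist-like), plus a
per-ligand baseline offset shared across all conformations, with an
independent per-cell Bernoulli docking failure.  The ligand-level offset
models affinity heterogeneity within a class: real per-class score
distributions span several score units, and because best-across-ensemble
aggregation averages away conformation-level noise but not ligand-level
variation, this term is what keeps class separation realistic (enrichment
well below AUC 1.0) under min-aggregation.  The defaults encode the
qualitative phenomenology of nuclear-receptor ensemble docking: agonists
score well against every receptor conformation, antagonists score well only
against antagonist-like conformations and often fail to dock into
agonist-like ones, and decoys score poorly everywhere.  Default set sizes
(118 agonists, 115 antagonists, 3000 decoys — an actives:decoys ratio near
1:30) and the pool of 12 conformations match a realistic screening
benchmark built from four MD trajectories with three cluster
representatives each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .score_data import LIGAND_CLASSES, LigandLabels, ScoreMatrix
from .struct_cluster import FrameSet

CONF_TYPES = ("agonist_like", "antagonist_like")

#: Class x conformation-type score means (docking-score units, lower=better).
DEFAULT_MEANS = {
    ("agonist", "agonist_like"): -11.0,
    ("agonist", "antagonist_like"): -11.0,
    ("antagonist", "agonist_like"): -6.0,
    ("antagonist", "antagonist_like"): -11.0,
    ("decoy", "agonist_like"): -4.0,
    ("decoy", "antagonist_like"): -4.0,
}

#: Per-cell docking-failure probabilities; antagonists frequently cannot be
#: docked into agonist-like conformations.
DEFAULT_FAILURE = {
    ("agonist", "agonist_like"): 0.0,
    ("agonist", "antagonist_like"): 0.0,
    ("antagonist", "agonist_like"): 0.3,
    ("antagonist", "antagonist_like"): 0.0,
    ("decoy", "agonist_like"): 0.0,
    ("decoy", "antagonist_like"): 0.0,
}


@dataclass(frozen=True)
class ScoreGenConfig:
    """Parameters of the synthetic docking-score benchmark."""

    n_agonists: int = 118
    n_antagonists: int = 115
    n_decoys: int = 3000
    n_agonist_like: int = 6
    n_antagonist_like: int = 6
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict = field(default_factory=dict)  # default 1.0 per (class, type)
    failure_probs: dict = field(default_factory=lambda: dict(DEFAULT_FAILURE))
    default_sd: float = 1.0
    ligand_sd: float = 2.0  # sd of the per-ligand affinity offset
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_agonists, self.n_antagonists, self.n_decoys):
            if n < 0:
                raise ValueError("ligand counts must be >= 0")
        if self.n_agonist_like + self.n_antagonist_like < 1:
            raise ValueError("conformation pool must be non-empty")
        if self.default_sd < 0 or self.ligand_sd < 0 or any(s < 0 for s in self.sds.values()):
            raise ValueError("standard deviations must be >= 0")
        for p in self.failure_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("failure probabilities must be in [0, 1]")

    def mean(self, cls: str, conf_type: str) -> float:
        return self.means.get((cls, conf_type), DEFAULT_MEANS[(cls, conf_type)])

    def sd(self, cls: str, conf_type: str) -> float:
        return self.sds.get((cls, conf_type), self.default_sd)

    def failure(self, cls: str, conf_type: str) -> float:
        return self.failure_probs.get((cls, conf_type), 0.0)

    def with_seed(self, seed: int) -> "ScoreGenConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth behind a generated matrix, for recovery tests."""

    conformation_types: dict  # conformation id -> type
    ligand_classes: dict  # ligand id -> class
    config: ScoreGenConfig

    def conformations_of_type(self, conf_type: str) -> list[str]:
        return [c for c, t in self.conformation_types.items() if t == conf_type]


def gen_score_matrix(
    config: ScoreGenConfig | None = None,
) -> tuple[ScoreMatrix, LigandLabels, PlantedTruth]:
    """Draw a synthetic score matrix, labels and planted ground truth.

    Fully reproducible from ``config.seed``; cells are Gaussian draws unless
    the per-cell Bernoulli failure fires, in which case the cell is marked
    failed.
    """
    config = config or ScoreGenConfig()
    rng = np.random.default_rng(config.seed)

    ligands: list[tuple[str, str]] = []
    for cls, n in (
        ("agonist", config.n_agonists),
        ("antagonist", config.n_antagonists),
        ("decoy", config.n_decoys),
    ):
        ligands += [(f"{cls}_{i:04d}", cls) for i in range(n)]
    confs: list[tuple[str, str]] = [
        (f"agonist_like_{i:02d}", "agonist_like") for i in range(config.n_agonist_like)
    ] + [
        (f"antagonist_like_{i:02d}", "antagonist_like")
        for i in range(config.n_antagonist_like)
    ]

    n_l, n_c = len(ligands), len(confs)
    offsets = rng.normal(0.0, config.ligand_sd, size=n_l) if config.ligand_sd > 0 else np.zeros(n_l)
    scores = np.empty((n_l, n_c))
    failed = np.zeros((n_l, n_c), dtype=bool)
    for j, (_, conf_type) in enumerate(confs):
        for cls in LIGAND_CLASSES:
            rows = [i for i, (_, c) in enumerate(ligands) if c == cls]
            if not rows:
                continue
            scores[rows, j] = rng.normal(
                config.mean(cls, conf_type), config.sd(cls, conf_type), size=len(rows)
            )
            p = config.failure(cls, conf_type)
            if p > 0:
                failed[rows, j] = rng.random(len(rows)) < p
    scores += offsets[:, None]

    matrix = ScoreMatrix(
        tuple(l for l, _ in ligands), tuple(c for c, _ in confs), scores, failed
    )
    labels = LigandLabels({l: c for l, c in ligands})
    truth = PlantedTruth(dict(confs), dict(ligands), config)
    return matrix, labels, truth


def gen_toy_frames(
    n_clusters: int,
    frames_per_cluster: int,
    jitter_sd: float = 0.1,
    center_separation: float = 10.0,
    seed: int = 0,
) -> tuple[FrameSet, np.ndarray]:
    """A toy protein+ligand FrameSet with planted conformational clusters.

    The system is a small rigid ligand surrounded by a shell of binding-site
    atoms (within 5 A) plus a distal shell.  For each planted cluster the
    binding-site atoms receive a cluster-specific non-rigid displacement
    field scaled so that inter-centre site RMSD is about
    ``center_separation``; each frame adds isotropic Gaussian jitter of
    ``jitter_sd`` to the protein atoms.  Ligand coordinates are held fixed
    so the binding-site selection is identical in every frame.

    Returns the FrameSet and the planted per-frame cluster labels.
    """
    if n_clusters < 1 or frames_per_cluster < 1:
        raise ValueError("counts must be >= 1")
    if center_separation <= 0:
        raise ValueError("center_separation must be positive")
    rng = np.random.default_rng(seed)

    # ligand: 5 heavy atoms near the origin
    lig = np.array(
        [[0.0, 0, 0], [1.4, 0, 0], [-1.4, 0, 0], [0, 1.4, 0], [0, -1.4, 0]]
    )
    # binding-site shell at ~4 A, distal shell at ~15 A (outside any 5 A site)
    def fib_sphere(n: int, radius: float) -> np.ndarray:
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = np.pi * (1 + 5**0.5) * k
        return radius * np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )

    site = fib_sphere(30, 4.0)
    distal = fib_sphere(20, 15.0)
    base = np.vstack([lig, site, distal])
    n_atoms = base.shape[0]
    is_ligand = np.zeros(n_atoms, bool)
    is_ligand[: len(lig)] = True
    site_slice = slice(len(lig), len(lig) + len(site))

    # per-cluster non-rigid displacement of the site shell; scaled so the
    # RMSD between two cluster centres is ~center_separation (independent
    # fields add in quadrature)
    per_atom_rms = center_separation / np.sqrt(2.0)
    centers = []
    for _ in range(n_clusters):
        disp = rng.normal(size=(len(site), 3))
        disp *= per_atom_rms / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        centers.append(disp)

    frames = []
    labels = []
    for c in range(n_clusters):
        for _ in range(frames_per_cluster):
            xyz = base.copy()
            xyz[site_slice] += centers[c]
            if jitter_sd > 0:
                xyz[~is_ligand] += rng.normal(0.0, jitter_sd, size=((~is_ligand).sum(), 3))
            frames.append(xyz)
            labels.append(c)

    elements = np.array(["C"] * n_atoms)
    fs = FrameSet.from_arrays(
        np.stack(frames), elements, is_ligand, name="toy_trajectory"
    )
    return fs, np.asarray(labels, dtype=int)
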
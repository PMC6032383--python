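"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (pairwise
counting, explicit subset enumeration) kept independent of the package's
vectorised code paths so they can serve as ground truth.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import settings

import ensemble_screen as es

settings.register_profile("suite", derandomize=True, max_examples=150, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_auc(actives, inactives) -> float:
    """O(|A||B|) pairwise AUC: win=1, tie=1/2; failure is worst, failures tie."""

    def is_failed(x):
        return x is None or (isinstance(x, float) and math.isnan(x))

    wins = 0.0
    for a in actives:
        for b in inactives:
            if is_failed(a) and is_failed(b):
                wins += 0.5
            elif is_failed(a):
                wins += 0.0
            elif is_failed(b):
                wins += 1.0
            elif a < b:  # lower score = better rank
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(actives) * len(inactives))


def naive_aggregate(matrix: es.ScoreMatrix, members):
    """Per-ligand best score via explicit loops; None = failed everywhere."""
    out = []
    for i in range(matrix.n_ligands):
        best = None
        for m in members:
            j = matrix.conformation_ids.index(m)
            if not matrix.failed[i, j]:
                s = matrix.scores[i, j]
                if best is None or s < best:
                    best = s
        out.append(best)
    return out


def naive_best_subset(matrix: es.ScoreMatrix, labels: es.LigandLabels, k, objective):
    """Enumerate all C(n, k) subsets with loops; same tie rule as the package."""
    actives = labels.ids_of(objective.active_class)
    decoys = labels.ids_of("decoy")
    others = labels.ids_of(objective.other_class) if objective.kind == "summed_auc" else None
    best = None
    for subset in combinations(matrix.conformation_ids, k):
        agg = dict(zip(matrix.ligand_ids, naive_aggregate(matrix, subset)))
        total = brute_auc([agg[l] for l in actives], [agg[l] for l in decoys])
        if others is not None:
            total += brute_auc([agg[l] for l in actives], [agg[l] for l in others])
        canon = tuple(sorted(subset))
        key = (-total, canon)
        if best is None or key < best[0]:
            best = (key, canon, total)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def crossdock():
    """The bundled 5x5 cross-docking example (matrix, labels, native map)."""
    return es.load_crossdock_example()


def write_pdb(path, frames, ligand_first_n=3, ligand_resname="LIG"):
    """Write frames as a multi-MODEL PDB with the first atoms as the ligand."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for m, xyz in enumerate(frames, 1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(xyz):
                if i < ligand_first_n:
                    resn, resi, elem, name = ligand_resname, 900, "C", f"C{i+1}"
                else:
                    resn, resi, elem, name = "ALA", i, ("C" if i % 2 else "N"), f"X{i}"
                fh.write(
                    f"ATOM  {i+1:5d} {name:<4s}{resn:>4s} A{resi:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def fib_sphere(n: int, radius: float) -> np.ndarray:
    """Near-uniform points on a sphere (fixture geometry for cavities)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def cube_shell(half=6.1, spacing=0.8, extent=6.5) -> np.ndarray:
    """Six dense atom planes enclosing a cubic cavity."""
    g = np.arange(-extent, extent + 1e-9, spacing)
    faces = []
    for d in range(3):
        for s in (-half, half):
            a, b = np.meshgrid(g, g)
            face = np.zeros((a.size, 3))
            face[:, d] = s
            face[:, (d + 1) % 3] = a.ravel()
            face[:, (d + 2) % 3] = b.ravel()
            faces.append(face)
    return np.vstack(faces)
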
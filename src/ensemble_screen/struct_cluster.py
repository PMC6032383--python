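"""Structure-side machinery for building receptor-conformation pools.

Covers: PDB ingestion into a :class:`FrameSet`, binding-site definition by a
distance cutoff around a bound ligand, heavy-atom RMSD with optional Kabsch
superposition, affinity-propagation clustering of trajectory frames on the
binding-site RMSD matrix, extraction of the exemplars of the most populated
clusters, average-linkage clustering of crystal structures by binding-site
similarity, and a grid/flood-fill estimate of pocket volume.

Distances and coordinates are in Angstrom throughout.  Binding-site atom
selections are frozen from a single reference frame so the RMSD atom set is
identical across all frames of a trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import binary_propagation
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

logger = logging.getLogger("ensemble_screen")

#: Element-keyed van der Waals radii (Angstrom); unknown elements fall back
#: to the carbon radius.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}
DEFAULT_VDW = 1.7

ATOM_TABLE_COLUMNS = ("atom_name", "element", "res_id", "res_name", "chain", "is_ligand")


class StructureError(ValueError):
    """Raised for malformed coordinate sets or empty selections."""


@dataclass(frozen=True)
class FrameSet:
    """An ordered set of coordinate frames over a fixed atom table.

    ``atom_table`` has columns atom_name, element, res_id, res_name, chain
    and is_ligand; ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom.
    """

    atom_table: pd.DataFrame
    coords: np.ndarray
    name: str = "frameset"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError(f"coords shape {coords.shape} is not (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise StructureError("a FrameSet needs at least one frame")
        if coords.shape[1] != len(self.atom_table):
            raise StructureError("coords atom count differs from atom table")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        missing = [c for c in ATOM_TABLE_COLUMNS if c not in self.atom_table.columns]
        if missing:
            raise StructureError(f"atom table missing columns: {missing}")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def elements(self) -> np.ndarray:
        return self.atom_table["element"].to_numpy(dtype=str)

    @property
    def is_ligand(self) -> np.ndarray:
        return self.atom_table["is_ligand"].to_numpy(dtype=bool)

    @property
    def heavy(self) -> np.ndarray:
        return ~np.isin(np.char.upper(self.elements), ("H", "D"))

    @staticmethod
    def from_arrays(
        coords,
        elements,
        is_ligand=None,
        *,
        res_ids=None,
        atom_names=None,
        name: str = "frameset",
    ) -> "FrameSet":
        """Build a FrameSet from bare arrays (synthetic systems, tests)."""
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        n = coords.shape[1]
        elements = np.asarray(elements, dtype=str)
        lig = np.zeros(n, bool) if is_ligand is None else np.asarray(is_ligand, bool)
        table = pd.DataFrame(
            {
                "atom_name": atom_names if atom_names is not None else [f"X{i}" for i in range(n)],
                "element": elements,
                "res_id": res_ids if res_ids is not None else np.arange(n),
                "res_name": np.where(lig, "LIG", "RES"),
                "chain": "A",
                "is_ligand": lig,
            }
        )
        return FrameSet(table, coords, name=name)


@dataclass(frozen=True)
class BindingSiteSpec:
    """A frozen binding-site atom selection.

    ``atom_indices`` are protein heavy atoms whose minimum distance to any
    ligand heavy atom, measured in ``reference_frame``, is <= ``cutoff``.
    """

    cutoff: float
    reference_frame: int
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise StructureError("cutoff must be positive")
        if len(self.atom_indices) == 0:
            raise StructureError("binding-site selection is empty")


@dataclass(frozen=True)
class ClusterAssignment:
    """Affinity-propagation output: exemplars, labels and populations."""

    exemplar_frame_indices: tuple[int, ...]
    labels: np.ndarray  # per-frame cluster index into exemplar_frame_indices
    populations: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        pops = np.asarray(self.populations, dtype=int)
        n_clusters = len(self.exemplar_frame_indices)
        if labels.min(initial=0) < 0 or labels.max(initial=-1) >= n_clusters:
            raise StructureError("label outside cluster range")
        if pops.sum() != labels.size:
            raise StructureError("populations do not sum to n_frames")
        for c, ex in enumerate(self.exemplar_frame_indices):
            if labels[ex] != c:
                raise StructureError(f"exemplar {ex} not member of its own cluster")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "populations", pops)

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_frame_indices)


class ConvergenceError(RuntimeError):
    """Affinity propagation failed to converge; carries the partial state."""

    def __init__(self, message: str, partial: ClusterAssignment | None):
        super().__init__(message)
        self.partial = partial


# ---------------------------------------------------------------------------
# PDB ingestion
# ---------------------------------------------------------------------------

def read_frames(paths, ligand_resname: str, name: str | None = None) -> FrameSet:
    """Read one or more (multi-MODEL) PDB files into a FrameSet.

    All models across all files must share the same atom composition; the
    residue name ``ligand_resname`` flags the bound ligand.  Alternate
    locations are resolved to the highest-occupancy copy.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(paths, (str, Path)):
        paths = [paths]
    stacks = []
    for p in paths:
        pdb = PDBFile.read(str(p))
        arr = pdb.get_structure(altloc="occupancy")
        if isinstance(arr, struc.AtomArray):
            arr = struc.stack([arr])
        stacks.append(arr)
    ref = stacks[0]
    for p, st in zip(paths, stacks):
        if st.array_length() != ref.array_length():
            raise StructureError(
                f"atom count mismatch: {Path(p).name} has {st.array_length()} "
                f"atoms, expected {ref.array_length()}"
            )
        if not (
            np.array_equal(st.atom_name, ref.atom_name)
            and np.array_equal(st.res_id, ref.res_id)
        ):
            raise StructureError(f"atom composition differs in {Path(p).name}")
    coords = np.concatenate([st.coord for st in stacks], axis=0)
    is_ligand = ref.res_name == ligand_resname
    if not is_ligand.any():
        raise StructureError(f"ligand residue {ligand_resname!r} not found")
    table = pd.DataFrame(
        {
            "atom_name": ref.atom_name,
            "element": np.char.capitalize(ref.element.astype(str)),
            "res_id": ref.res_id,
            "res_name": ref.res_name,
            "chain": ref.chain_id,
            "is_ligand": is_ligand,
        }
    )
    return FrameSet(table, coords, name=name or Path(paths[0]).stem)


def write_frames(frames: FrameSet, path, frame_indices=None) -> None:
    """Write selected frames (default: all) as a multi-MODEL PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    idx = list(range(frames.n_frames)) if frame_indices is None else list(frame_indices)
    t = frames.atom_table
    arrays = []
    for i in idx:
        arr = struc.AtomArray(frames.n_atoms)
        arr.coord = frames.coords[i]
        arr.atom_name = t["atom_name"].to_numpy(dtype=str)
        arr.element = np.char.upper(t["element"].to_numpy(dtype=str))
        arr.res_id = t["res_id"].to_numpy(dtype=int)
        arr.res_name = t["res_name"].to_numpy(dtype=str)
        arr.chain_id = t["chain"].to_numpy(dtype=str)
        arr.hetero = t["is_ligand"].to_numpy(dtype=bool)
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Binding site and RMSD
# ---------------------------------------------------------------------------

def select_binding_site(
    frames: FrameSet, cutoff: float = 5.0, reference_frame: int = 0
) -> BindingSiteSpec:
    """Protein heavy atoms within ``cutoff`` of any ligand heavy atom.

    The selection is made once, in ``reference_frame``, and reused for every
    frame so that RMSD values are computed over a fixed atom set.
    """
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    if not 0 <= reference_frame < frames.n_frames:
        raise StructureError(f"reference frame {reference_frame} out of range")
    lig_heavy = frames.is_ligand & frames.heavy
    prot_heavy = ~frames.is_ligand & frames.heavy
    if not lig_heavy.any():
        raise StructureError("no ligand heavy atoms flagged")
    xyz = frames.coords[reference_frame]
    tree = cKDTree(xyz[lig_heavy])
    dmin, _ = tree.query(xyz[prot_heavy])
    sel = np.flatnonzero(prot_heavy)[dmin <= cutoff]
    if sel.size == 0:
        raise StructureError(f"no protein heavy atoms within {cutoff} A of the ligand")
    return BindingSiteSpec(cutoff, reference_frame, tuple(int(i) for i in sel))


def rmsd(frame_a, frame_b, atom_indices, superpose: bool = False) -> float:
    """Root-mean-square deviation over selected atoms, in Angstrom.

    With ``superpose=True`` an optimal least-squares rigid-body (Kabsch)
    superposition on the same atoms is applied first.
    """
    idx = np.asarray(list(atom_indices), dtype=int)
    if idx.size == 0:
        raise StructureError("empty atom index set")
    a = np.asarray(frame_a, dtype=float)[idx]
    b = np.asarray(frame_b, dtype=float)[idx]
    raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    if not superpose:
        return raw
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # exact alignments
        _, rssd = Rotation.align_vectors(a_c, b_c)
    # superposition can only reduce the deviation; clamping removes the
    # ~1e-7 numerical floor align_vectors leaves on exact matches
    return min(raw, float(rssd / np.sqrt(idx.size)))


def pairwise_rmsd_matrix(
    frames: FrameSet, site: BindingSiteSpec, superpose: bool = True
) -> np.ndarray:
    """Symmetric n_frames x n_frames RMSD matrix on the site atom set."""
    n = frames.n_frames
    idx = site.atom_indices
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rmsd(
                frames.coords[i], frames.coords[j], idx, superpose=superpose
            )
    return out


# ---------------------------------------------------------------------------
# Affinity propagation
# ---------------------------------------------------------------------------

def affinity_propagation(
    distance_matrix,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
) -> ClusterAssignment:
    """Cluster items by affinity-propagation message passing.

    The similarity is ``s(i, j) = -d(i, j)**2`` with the self-similarity set
    to ``preference`` (default: median of the off-diagonal similarities —
    the conventional choice yielding a moderate number of clusters).  The
    update is fully deterministic; convergence means the exemplar set was
    stable for ``convergence_iter`` consecutive iterations.

    Raises
    ------
    ConvergenceError
        If no stable exemplar set emerges within ``max_iter`` iterations;
        the exception carries the last assignment as ``partial``.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise StructureError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise StructureError("distance matrix must be symmetric")
    if not 0.5 <= damping < 1.0:
        raise StructureError("damping must be in [0.5, 1)")
    n = D.shape[0]
    if n == 1:
        return ClusterAssignment((0,), np.zeros(1, int), np.ones(1, int))

    S = -(D.astype(float) ** 2)
    if preference == "median":
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, float(preference))
    return _affinity_propagation_on_similarity(
        S, damping=damping, max_iter=max_iter, convergence_iter=convergence_iter
    )


def _affinity_propagation_on_similarity(
    S: np.ndarray, damping: float, max_iter: int, convergence_iter: int
) -> ClusterAssignment:
    """Message passing on a prepared similarity matrix (diagonal = preference)."""
    n = S.shape[0]
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    exemplars: np.ndarray | None = None
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first = AS.max(axis=1)
        first_k = AS.argmax(axis=1)
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        R_new = S - first[:, None]
        R_new[idx, first_k] = S[idx, first_k] - second
        R = damping * R + (1 - damping) * R_new
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        A_new = np.minimum(0.0, col[None, :] - Rp)
        A_new[idx, idx] = col - R.diagonal()  # sum of positive off-diag responsibilities
        A = damping * A + (1 - damping) * A_new

        ex = np.flatnonzero(A.diagonal() + R.diagonal() > 0)
        if exemplars is not None and ex.size and np.array_equal(ex, exemplars):
            stable += 1
            if stable >= convergence_iter:
                return _finalise_assignment(S, ex)
        else:
            stable = 0
        exemplars = ex

    partial = (
        _finalise_assignment(S, exemplars)
        if exemplars is not None and exemplars.size
        else None
    )
    raise ConvergenceError(
        f"affinity propagation did not converge in {max_iter} iterations", partial
    )


def _finalise_assignment(S: np.ndarray, exemplars: np.ndarray) -> ClusterAssignment:
    exemplars = exemplars.copy()
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)  # exemplars own themselves
    # refine each exemplar to the member maximising summed within-cluster
    # similarity (the closing step of the standard procedure), then reassign
    for k in range(exemplars.size):
        members = np.flatnonzero(labels == k)
        j = np.argmax(S[members[:, None], members].sum(axis=0))
        exemplars[k] = members[j]
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    pops = np.bincount(labels, minlength=exemplars.size)
    return ClusterAssignment(tuple(int(e) for e in exemplars), labels, pops)


def representatives(assignment: ClusterAssignment, n: int = 3) -> list[int]:
    """Exemplar frames of the ``n`` most populated clusters.

    Ordered by descending population; population ties resolve to the lower
    cluster index.  If fewer than ``n`` clusters exist, all exemplars are
    returned with a logged warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(
        range(assignment.n_clusters), key=lambda c: (-int(assignment.populations[c]), c)
    )
    if assignment.n_clusters < n:
        logger.warning(
            "requested %d representatives but only %d clusters exist",
            n,
            assignment.n_clusters,
        )
    return [assignment.exemplar_frame_indices[c] for c in order[:n]]


# ---------------------------------------------------------------------------
# Crystal-structure clustering by binding-site similarity
# ---------------------------------------------------------------------------

def cluster_structures_by_site(
    structures: list[FrameSet], n_clusters: int = 5, cutoff: float = 5.0
) -> list[str]:
    """Pick ``n_clusters`` medoid structures by binding-site similarity.

    Structures (single-frame FrameSets) are mapped onto a common atom set by
    (chain, residue id, atom name); the binding site is resolved on the
    first structure's ligand at ``cutoff``.  Average-linkage hierarchical
    clustering on the pairwise superposed site RMSD is cut to ``n_clusters``
    and each cluster contributes its medoid (minimum summed intra-cluster
    distance; ties to the lower structure index).

    With an all-zero distance matrix (identical structures) the first
    ``n_clusters`` structure names are returned — the documented degenerate
    rule.
    """
    if not structures:
        raise StructureError("no structures given")
    if n_clusters < 1 or n_clusters > len(structures):
        raise StructureError(f"n_clusters={n_clusters} out of range")

    def keys_of(fs: FrameSet, mask: np.ndarray) -> dict[tuple, int]:
        t = fs.atom_table
        return {
            (t["chain"].iat[i], int(t["res_id"].iat[i]), t["atom_name"].iat[i]): i
            for i in np.flatnonzero(mask)
        }

    ref = structures[0]
    maps = [keys_of(fs, ~fs.is_ligand & fs.heavy) for fs in structures]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if not common:
        raise StructureError("no common binding-site atoms across structures")

    lig_heavy = ref.is_ligand & ref.heavy
    if not lig_heavy.any():
        raise StructureError("reference structure has no flagged ligand heavy atoms")
    tree = cKDTree(ref.coords[0][lig_heavy])
    site_keys = sorted(
        k for k in common
        if tree.query(ref.coords[0][maps[0][k]])[0] <= cutoff
    )
    if not site_keys:
        raise StructureError("common binding-site atom set is empty at this cutoff")

    site_coords = [
        fs.coords[0][[m[k] for k in site_keys]] for fs, m in zip(structures, maps)
    ]
    names = [fs.name for fs in structures]
    n = len(structures)
    D = np.zeros((n, n))
    all_idx = np.arange(len(site_keys))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rmsd(site_coords[i], site_coords[j], all_idx, superpose=True)

    if np.allclose(D, 0.0):
        return names[:n_clusters]
    Z = linkage(squareform(D, checks=False), method="average")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    medoids: list[str] = []
    for c in sorted(set(flat)):
        members = np.flatnonzero(flat == c)
        sums = D[np.ix_(members, members)].sum(axis=1)
        medoids.append(names[members[int(np.argmin(sums))]])
    if len(medoids) < n_clusters:
        logger.warning(
            "hierarchical cut yielded %d clusters (< %d requested)",
            len(medoids),
            n_clusters,
        )
    return medoids


# ---------------------------------------------------------------------------
# Pocket volume
# ---------------------------------------------------------------------------

def pocket_volume(
    frames: FrameSet,
    site: BindingSiteSpec,
    frame_index: int = 0,
    grid_spacing: float = 0.5,
    probe_radius: float = 1.4,
) -> float:
    """Enclosed cavity volume around the binding site, in cubic Angstrom.

    A cubic grid spans the bounding box of the site atoms padded by the
    probe radius.  A grid point is *free* when it lies farther than
    (vdW radius + probe radius) from every protein atom; free points
    reachable from the box boundary by 6-connected flood fill are open
    solvent and are discarded.  The remaining enclosed free points, times
    the voxel volume, estimate the pocket volume.
    """
    xyz = frames.coords[frame_index]
    prot = ~frames.is_ligand
    site_xyz = xyz[list(site.atom_indices)]
    lo = site_xyz.min(axis=0) - probe_radius
    hi = site_xyz.max(axis=0) + probe_radius
    if np.any(hi - lo <= grid_spacing):
        raise StructureError("degenerate bounding box for pocket grid")

    axes = [np.arange(lo[d], hi[d] + grid_spacing / 2, grid_spacing) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    occupied = np.zeros(pts.shape[0], dtype=bool)
    tree = cKDTree(pts)
    elements = np.char.capitalize(frames.elements[prot].astype(str))
    for elem in np.unique(elements):
        radius = VDW_RADII.get(elem, DEFAULT_VDW) + probe_radius
        atom_xyz = xyz[prot][elements == elem]
        for hit in tree.query_ball_point(atom_xyz, radius):
            occupied[hit] = True

    free = (~occupied).reshape(shape)
    boundary = np.zeros(shape, dtype=bool)
    for d in range(3):
        sl = [slice(None)] * 3
        sl[d] = 0
        boundary[tuple(sl)] = True
        sl[d] = -1
        boundary[tuple(sl)] = True
    open_solvent = binary_propagation(boundary & free, mask=free)
    enclosed = free & ~open_solvent
    return float(enclosed.sum()) * grid_spacing**3
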
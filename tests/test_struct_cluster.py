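"""Frames, binding sites, RMSD, affinity propagation and pocket volume."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import ensemble_screen as es
from ensemble_screen.struct_cluster import StructureError
from conftest import cube_shell, fib_sphere, write_pdb


class TestReadFrames:
    def test_single_model(self, tmp_path):
        rng = np.random.default_rng(0)
        p = tmp_path / "one.pdb"
        write_pdb(p, rng.normal(scale=3, size=(10, 3)))
        fs = es.read_frames(p, "LIG")
        assert fs.n_frames == 1 and fs.n_atoms == 10 and fs.is_ligand.sum() == 3

    def test_multi_model_shared_table(self, tmp_path):
        rng = np.random.default_rng(1)
        p = tmp_path / "multi.pdb"
        frames = rng.normal(scale=3, size=(3, 10, 3))
        write_pdb(p, frames)
        fs = es.read_frames(p, "LIG")
        assert fs.n_frames == 3
        assert np.allclose(fs.coords, np.round(frames, 3))

    def test_atom_count_mismatch_rejected(self, tmp_path):
        rng = np.random.default_rng(2)
        a, b = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(a, rng.normal(size=(10, 3)))
        write_pdb(b, rng.normal(size=(12, 3)))
        with pytest.raises(StructureError, match="mismatch"):
            es.read_frames([a, b], "LIG")

    def test_missing_ligand_rejected(self, tmp_path):
        p = tmp_path / "nolig.pdb"
        write_pdb(p, np.zeros((5, 3)), ligand_first_n=0)
        with pytest.raises(StructureError, match="not found"):
            es.read_frames(p, "LIG")

    def test_write_then_read_round_trip(self, tmp_path):
        from ensemble_screen.struct_cluster import write_frames

        fs, _ = es.gen_toy_frames(2, 2, jitter_sd=0.3, center_separation=3.0, seed=6)
        p = tmp_path / "reps.pdb"
        write_frames(fs, p, frame_indices=[0, 3])
        back = es.read_frames(p, "LIG")
        assert back.n_frames == 2 and back.n_atoms == fs.n_atoms
        assert np.allclose(back.coords, np.round(fs.coords[[0, 3]], 3), atol=1e-3)


class TestBindingSite:
    def _system(self, protein_xyz, elements=None):
        xyz = np.vstack([[[0.0, 0, 0]], protein_xyz])
        elems = ["C"] + (elements or ["C"] * len(protein_xyz))
        lig = np.zeros(len(xyz), bool)
        lig[0] = True
        return es.FrameSet.from_arrays(xyz, elems, lig)

    def test_cutoff_is_inclusive(self):
        fs = self._system([[3.0, 0, 0], [4.9, 0, 0], [5.1, 0, 0]])
        site = es.select_binding_site(fs, cutoff=5.0)
        assert site.atom_indices == (1, 2)

    def test_hydrogens_excluded(self):
        fs = self._system([[2.0, 0, 0], [3.0, 0, 0]], elements=["H", "C"])
        site = es.select_binding_site(fs, cutoff=5.0)
        assert site.atom_indices == (2,)

    def test_empty_selection_rejected(self):
        fs = self._system([[3.0, 0, 0]])
        with pytest.raises(StructureError, match="no protein heavy atoms"):
            es.select_binding_site(fs, cutoff=0.1)


class TestRmsd:
    def test_identical_frames_zero(self):
        a = np.random.default_rng(0).normal(size=(8, 3))
        assert es.rmsd(a, a, range(8)) == 0.0

    def test_translation_gives_norm(self):
        a = np.random.default_rng(1).normal(size=(8, 3))
        assert es.rmsd(a, a + [3.0, 4.0, 0.0], range(8)) == pytest.approx(5.0)

    def test_rigid_motion_removed_by_superposition(self):
        a = np.random.default_rng(2).normal(size=(8, 3))
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0])
        b = rot.apply(a) + [1.0, -2.0, 3.0]
        assert es.rmsd(a, b, range(8), superpose=True) == pytest.approx(0.0, abs=1e-6)

    def test_empty_index_set_rejected(self):
        with pytest.raises(StructureError):
            es.rmsd(np.zeros((3, 3)), np.zeros((3, 3)), [])

    @given(seed=st.integers(0, 300))
    @settings(max_examples=40)
    def test_pseudometric_and_superposition_bound(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 6, 3))
        idx = range(6)
        dab = es.rmsd(a, b, idx)
        dba = es.rmsd(b, a, idx)
        assert dab == pytest.approx(dba)
        assert dab <= es.rmsd(a, c, idx) + es.rmsd(c, b, idx) + 1e-12
        assert es.rmsd(a, b, idx, superpose=True) <= dab + 1e-9

    def test_pairwise_matrix_matches_per_pair(self):
        fs, _ = es.gen_toy_frames(2, 3, jitter_sd=0.5, center_separation=4.0, seed=3)
        site = es.select_binding_site(fs)
        mat = es.pairwise_rmsd_matrix(fs, site)
        assert np.allclose(mat, mat.T) and np.all(np.diag(mat) == 0)
        for i in range(fs.n_frames):
            for j in range(fs.n_frames):
                assert mat[i, j] == pytest.approx(
                    es.rmsd(fs.coords[i], fs.coords[j], site.atom_indices, superpose=True)
                )

    def test_identical_frames_zero_matrix(self):
        fs, _ = es.gen_toy_frames(1, 2, jitter_sd=0.0, center_separation=1.0, seed=0)
        site = es.select_binding_site(fs)
        assert np.all(es.pairwise_rmsd_matrix(fs, site) == 0.0)


class TestAffinityPropagation:
    def test_single_point(self):
        a = es.affinity_propagation(np.zeros((1, 1)))
        assert a.exemplar_frame_indices == (0,) and a.populations.tolist() == [1]

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        pts = np.vstack([c + rng.normal(0, 0.1, size=(10, 3)) for c in centers])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        a = es.affinity_propagation(d)
        assert a.n_clusters == 3
        # labels match planted membership up to permutation
        planted = np.repeat([0, 1, 2], 10)
        for c in range(3):
            assert len(set(a.labels[planted == c])) == 1

    def test_matches_sklearn_reference(self):
        """Exemplars and labels identical to the sklearn implementation.

        sklearn perturbs its similarity input with tiny random noise to
        break degenerate symmetries, so the controlled comparison feeds the
        identical (noise-injected) similarity matrix to both message loops.
        """
        from sklearn.cluster import AffinityPropagation
        from sklearn.utils import check_random_state

        from ensemble_screen.struct_cluster import _affinity_propagation_on_similarity

        rng = np.random.default_rng(5)
        for _ in range(5):
            pts = rng.normal(size=(20, 3))
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            s = -(d**2)
            pref = float(np.median(s[~np.eye(20, dtype=bool)]))
            np.fill_diagonal(s, pref)
            noise = check_random_state(0).standard_normal((20, 20))
            s_noisy = s + (np.finfo(s.dtype).eps * s + np.finfo(s.dtype).tiny * 100) * noise
            ours = _affinity_propagation_on_similarity(
                s_noisy.copy(), damping=0.9, max_iter=1000, convergence_iter=50
            )
            ref = AffinityPropagation(
                affinity="precomputed", damping=0.9, preference=pref,
                max_iter=1000, convergence_iter=50, random_state=0,
            ).fit(s)
            assert sorted(ours.exemplar_frame_indices) == sorted(ref.cluster_centers_indices_)
            ours_exemplar_of = np.array(ours.exemplar_frame_indices)[ours.labels]
            ref_exemplar_of = ref.cluster_centers_indices_[ref.labels_]
            assert np.array_equal(ours_exemplar_of, ref_exemplar_of)

    def test_exemplar_count_monotone_in_preference(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(15, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        s = -(d**2)
        off = s[~np.eye(15, dtype=bool)]
        counts = []
        for pref in [off.min() * 3, off.min(), np.median(off), off.max()]:
            counts.append(es.affinity_propagation(d, preference=float(pref)).n_clusters)
        assert counts == sorted(counts)

    def test_nonconvergence_carries_partial_state(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        with pytest.raises(es.ConvergenceError) as exc:
            es.affinity_propagation(d, max_iter=3, convergence_iter=50)
        assert exc.value.partial is None or isinstance(exc.value.partial, es.ClusterAssignment)

    def test_damping_validated(self):
        with pytest.raises(StructureError):
            es.affinity_propagation(np.zeros((2, 2)), damping=0.2)


class TestRepresentatives:
    def _assignment(self, pops):
        # synthetic assignment with given populations; exemplar = first member
        labels = np.concatenate([[c] * p for c, p in enumerate(pops)])
        exemplars = np.cumsum([0] + list(pops[:-1]))
        return es.ClusterAssignment(tuple(int(e) for e in exemplars), labels, np.array(pops))

    def test_top_populated_first(self):
        a = self._assignment([5, 50, 30, 15])
        reps = es.representatives(a, n=3)
        assert reps == [a.exemplar_frame_indices[1], a.exemplar_frame_indices[2], a.exemplar_frame_indices[3]]

    def test_fewer_clusters_than_requested_warns(self, caplog):
        a = self._assignment([4])
        with caplog.at_level("WARNING", logger="ensemble_screen"):
            reps = es.representatives(a, n=3)
        assert reps == [0] and any("representatives" in r.message for r in caplog.records)

    def test_population_tie_lower_cluster_first(self):
        a = self._assignment([10, 10])
        assert es.representatives(a, n=2) == [a.exemplar_frame_indices[0], a.exemplar_frame_indices[1]]


class TestClusterStructuresBySite:
    def _family_structures(self, rng, n_per_family=4, families=2, spread=6.0):
        base = rng.normal(scale=3, size=(12, 3))
        lig = np.zeros(12, bool)
        lig[:3] = True
        shifts = [rng.normal(size=(9, 3)) * 0] + [
            rng.normal(size=(9, 3)) / np.sqrt(3) * spread for _ in range(families - 1)
        ]
        structs = []
        for f in range(families):
            for i in range(n_per_family):
                xyz = base.copy()
                xyz[3:] += shifts[f] + rng.normal(scale=0.05, size=(9, 3))
                structs.append(
                    es.FrameSet.from_arrays(xyz, ["C"] * 12, lig, name=f"f{f}s{i}")
                )
        return structs

    def test_each_structure_own_medoid_when_k_equals_n(self):
        rng = np.random.default_rng(8)
        structs = self._family_structures(rng, n_per_family=2)
        med = es.cluster_structures_by_site(structs, n_clusters=4, cutoff=30.0)
        assert sorted(med) == sorted(s.name for s in structs)

    def test_two_planted_families_one_medoid_each(self):
        rng = np.random.default_rng(9)
        structs = self._family_structures(rng)
        med = es.cluster_structures_by_site(structs, n_clusters=2, cutoff=30.0)
        assert len(med) == 2
        assert {m[:2] for m in med} == {"f0", "f1"}

    def test_identical_structures_degenerate_rule(self):
        rng = np.random.default_rng(10)
        base = rng.normal(scale=3, size=(12, 3))
        lig = np.zeros(12, bool)
        lig[:3] = True
        structs = [
            es.FrameSet.from_arrays(base, ["C"] * 12, lig, name=f"s{i}") for i in range(5)
        ]
        assert es.cluster_structures_by_site(structs, n_clusters=3, cutoff=30.0) == [
            "s0", "s1", "s2",
        ]


class TestPocketVolume:
    def _frameset(self, xyz):
        return es.FrameSet.from_arrays(xyz, ["C"] * len(xyz)), es.BindingSiteSpec(
            5.0, 0, tuple(range(len(xyz)))
        )

    def test_cubic_cavity(self):
        fs, site = self._frameset(cube_shell())
        v = es.pocket_volume(fs, site)
        assert v == pytest.approx(216.0, rel=0.10)

    def test_spherical_cavity(self):
        fs, site = self._frameset(fib_sphere(2000, 7.1))
        v = es.pocket_volume(fs, site)
        assert v == pytest.approx(4 / 3 * np.pi * 4**3, rel=0.10)

    def test_solid_block_no_cavity(self):
        g = np.arange(-3, 3.01, 1.0)
        xx, yy, zz = np.meshgrid(g, g, g)
        fs, site = self._frameset(np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]))
        assert es.pocket_volume(fs, site) == 0.0

    def test_grid_convergence(self):
        fs, site = self._frameset(fib_sphere(2000, 7.1))
        v_coarse = es.pocket_volume(fs, site, grid_spacing=0.5)
        v_fine = es.pocket_volume(fs, site, grid_spacing=0.25)
        assert abs(v_coarse - v_fine) / v_fine < 0.10
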
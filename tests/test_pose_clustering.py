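"""RMSD matrices, DBSCAN vs reference implementations, medoids, contacts."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import brute_force_dbscan, canonical_labels
from xenbkit import struct_io, synthetic_data
from xenbkit.pose_clustering import (
    ClusterResult,
    RMSDMatrix,
    contact_residues,
    dbscan,
    ligand_rmsd_matrix,
    medoid,
)


def matrix_from_points(points: np.ndarray) -> RMSDMatrix:
    dist = squareform(pdist(points))
    return RMSDMatrix(list(range(len(points))), dist)


class TestLigandRmsdMatrix:
    def test_identical_frames_zero_matrix(self, pocket_complex):
        frames = np.repeat(pocket_complex.coords[None, :, :], 4, axis=0)
        traj = struct_io.Trajectory(pocket_complex, frames)
        ligand = struct_io.select_atoms(pocket_complex, "resname TNT and not element H")
        fit = struct_io.select_atoms(pocket_complex, "resname FMN")
        matrix = ligand_rmsd_matrix(traj, ligand, fit)
        np.testing.assert_allclose(matrix.values, 0.0, atol=1e-10)

    def test_pure_ligand_translation_is_its_norm(self, pocket_complex):
        frames = np.repeat(pocket_complex.coords[None, :, :], 2, axis=0)
        ligand = struct_io.select_atoms(pocket_complex, "resname TNT and not element H")
        frames[1, list(ligand.indices)] += np.array([2.0, 0.0, 0.0])
        traj = struct_io.Trajectory(pocket_complex, frames)
        fit = struct_io.select_atoms(pocket_complex, "resname FMN")
        matrix = ligand_rmsd_matrix(traj, ligand, fit)
        assert matrix.values[0, 1] == pytest.approx(2.0, abs=1e-8)

    def test_symmetry_on_synthetic_data(self, two_mode_trajectory):
        topo = two_mode_trajectory.topology
        ligand = struct_io.select_atoms(topo, "resname TNT and not element H")
        fit = struct_io.select_atoms(topo, "resname FMN")
        sub = struct_io.Trajectory(topo, two_mode_trajectory.frames[:20])
        matrix = ligand_rmsd_matrix(sub, ligand, fit)
        np.testing.assert_allclose(matrix.values, matrix.values.T, atol=1e-9)

    def test_hydrogens_in_ligand_selection_rejected(self, pocket_complex):
        frames = pocket_complex.coords[None, :, :]
        traj = struct_io.Trajectory(pocket_complex, frames)
        ligand = struct_io.select_atoms(pocket_complex, "resname TNT")
        fit = struct_io.select_atoms(pocket_complex, "resname FMN")
        with pytest.raises(ValueError, match="hydrogen"):
            ligand_rmsd_matrix(traj, ligand, fit)


class TestDbscan:
    def test_two_well_separated_groups(self):
        rng = np.random.default_rng(0)
        group_a = rng.normal(0.0, 0.2, (6, 3))
        group_b = rng.normal(0.0, 0.2, (6, 3)) + np.array([8.0, 0.0, 0.0])
        matrix = matrix_from_points(np.vstack([group_a, group_b]))
        result = dbscan(matrix, eps=1.5, min_points=5)
        assert result.n_clusters == 2
        assert np.sum(result.labels == -1) == 0
        want = brute_force_dbscan(matrix.values, 1.5, 5)
        np.testing.assert_array_equal(
            canonical_labels(result.labels), canonical_labels(want)
        )

    def test_too_few_points_all_noise(self):
        matrix = matrix_from_points(np.random.default_rng(1).normal(0, 0.1, (4, 3)))
        result = dbscan(matrix, eps=1.5, min_points=5)
        assert result.n_clusters == 0
        assert np.all(result.labels == -1)

    def test_defaults_match_published_parameters(self):
        import inspect

        sig = inspect.signature(dbscan)
        assert sig.parameters["eps"].default == 1.5
        assert sig.parameters["min_points"].default == 5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reference_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        dim = int(rng.integers(2, 5))
        points = rng.uniform(0, 6, (n, dim))
        dist = squareform(pdist(points))
        eps = float(rng.uniform(0.3, 2.0))
        min_points = int(rng.integers(2, 8))
        matrix = RMSDMatrix(list(range(n)), dist)
        got = dbscan(matrix, eps, min_points).labels
        want = brute_force_dbscan(dist, eps, min_points)
        np.testing.assert_array_equal(canonical_labels(got), canonical_labels(want))

    @pytest.mark.parametrize("seed", range(5))
    def test_core_structure_matches_sklearn(self, seed):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(100 + seed)
        points = rng.uniform(0, 5, (80, 3))
        dist = squareform(pdist(points))
        eps, min_points = 0.9, 4
        ours = dbscan(RMSDMatrix(list(range(80)), dist), eps, min_points)
        sk = sklearn_cluster.DBSCAN(
            eps=eps, min_samples=min_points, metric="precomputed"
        ).fit(dist)
        # noise sets agree; core points carry the same partition
        np.testing.assert_array_equal(ours.labels == -1, sk.labels_ == -1)
        core = np.zeros(80, dtype=bool)
        core[sk.core_sample_indices_] = True
        np.testing.assert_array_equal(
            canonical_labels(ours.labels[core]), canonical_labels(sk.labels_[core])
        )

    def test_label_partition_invariant_to_frame_order(self):
        rng = np.random.default_rng(42)
        points = np.vstack(
            [rng.normal(0, 0.3, (8, 2)), rng.normal(5, 0.3, (8, 2))]
        )
        dist = squareform(pdist(points))
        base = dbscan(RMSDMatrix(list(range(16)), dist), 1.5, 5).labels
        perm = rng.permutation(16)
        permuted = dist[np.ix_(perm, perm)]
        shuffled = dbscan(RMSDMatrix(list(range(16)), permuted), 1.5, 5).labels
        unshuffled = np.empty(16, dtype=int)
        unshuffled[perm] = shuffled
        np.testing.assert_array_equal(
            canonical_labels(base), canonical_labels(unshuffled)
        )

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            RMSDMatrix([0, 1], values)

    def test_every_cluster_has_min_points_members(self):
        rng = np.random.default_rng(7)
        points = rng.uniform(0, 4, (60, 2))
        dist = squareform(pdist(points))
        result = dbscan(RMSDMatrix(list(range(60)), dist), 0.8, 5)
        for label in range(result.n_clusters):
            assert np.sum(result.labels == label) >= 5


class TestMedoid:
    def test_singleton(self):
        matrix = matrix_from_points(np.zeros((1, 3)))
        assert medoid(matrix, [0]) == 0

    def test_forced_by_distance_sums(self):
        values = np.array(
            [[0.0, 1.0, 1.0], [1.0, 0.0, 2.0], [1.0, 2.0, 0.0]]
        )
        matrix = RMSDMatrix([1, 2, 3], values)
        assert medoid(matrix, [1, 2, 3]) == 1

    def test_unknown_member_rejected(self):
        matrix = matrix_from_points(np.zeros((2, 3)))
        with pytest.raises(KeyError):
            medoid(matrix, [0, 99])


class TestPoseModeRecovery:
    @pytest.mark.parametrize(
        "k,displacements,seed",
        [
            (1, [(0.0, 0.0, 0.0)], 21),
            (2, [(0.0, 0.0, 0.0), (4.5, 0.0, 0.0)], 22),
            (3, [(0.0, 0.0, 0.0), (4.5, 0.0, 0.0), (0.0, 4.5, 0.0)], 23),
        ],
    )
    def test_planted_modes_recovered(self, k, displacements, seed):
        modes = [synthetic_data.PoseMode(d, 1.0 / k, 0.4) for d in displacements]
        recipe = synthetic_data.ComplexRecipe(
            n_frames=40 * k, pose_modes=modes, seed=seed
        )
        traj = synthetic_data.make_complex_trajectory(recipe)
        ligand = struct_io.select_atoms(traj.topology, "resname TNT and not element H")
        fit = struct_io.select_atoms(traj.topology, "resname FMN")
        matrix = ligand_rmsd_matrix(traj, ligand, fit)
        result = dbscan(matrix)  # library defaults
        assert result.n_clusters == k
        assert np.mean(result.labels == -1) <= 0.05
        # medoid ligand centroids within one mode sd of their mode center
        lig_idx = np.array(ligand.indices)
        base = synthetic_data.make_pocket_complex().coords[lig_idx].mean(axis=0)
        for frame in result.medoid_frames:
            centroid = traj.frames[frame][lig_idx].mean(axis=0)
            nearest = min(
                np.linalg.norm(centroid - base - np.asarray(d))
                for d in displacements
            )
            assert nearest < 0.4


class TestContacts:
    def _complex_with_probe(self, pocket_complex, distance):
        """Append a probe residue at a controlled distance from a ligand atom."""
        ligand = struct_io.select_atoms(pocket_complex, "resname TNT and name C1")
        c1 = pocket_complex.coords[ligand.indices[0]]
        probe = struct_io.Atom(
            "O", "O", "HOH", 900, "A", c1 + np.array([0.0, 0.0, -1.0]) * distance
        )
        return struct_io.Structure(pocket_complex.atoms + [probe])

    def test_boundary_inside(self, pocket_complex):
        structure = self._complex_with_probe(pocket_complex, 2.9)
        ligand = struct_io.select_atoms(structure, "resname TNT")
        contacts = contact_residues(structure, ligand, 3.0)
        assert ("A", 900, "HOH") in contacts.residues

    def test_boundary_outside(self, pocket_complex):
        structure = self._complex_with_probe(pocket_complex, 3.1)
        ligand = struct_io.select_atoms(structure, "resname TNT")
        contacts = contact_residues(structure, ligand, 3.0)
        assert ("A", 900, "HOH") not in contacts.residues

    def test_generated_pocket_has_exactly_three_contacts(self, pocket_complex):
        ligand = struct_io.select_atoms(pocket_complex, "resname TNT")
        contacts = contact_residues(pocket_complex, ligand, 3.0)
        assert contacts.residues == [
            ("A", 65, "TYR"),
            ("A", 129, "LEU"),
            ("A", 335, "TYR"),
        ]

    def test_empty_ligand_rejected(self, pocket_complex):
        empty = struct_io.select_atoms(pocket_complex, "resname XYZ")
        with pytest.raises(ValueError, match="empty"):
            contact_residues(pocket_complex, empty)
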
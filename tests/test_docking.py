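"""Pose clustering, energy normalization and contact/epitope mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carragel.docking import (
    EPITOPES,
    Pose,
    cluster_poses,
    contact_residues,
    count_interacting_disaccharides,
    energy_per_disaccharide,
    population_energy_table,
    read_poses,
    true_positives,
    write_poses,
)
from carragel.synthetic import PoseCloudSpec, make_pose_cloud

from conftest import make_structure


def atom_pose(xyz, energy=-1.0, element="C"):
    return Pose((element,), np.array([xyz], dtype=float), energy,
                disaccharide_map=np.array([1]))


@pytest.fixture(scope="module")
def three_cluster_poses():
    spec = PoseCloudSpec(
        cluster_centres=[(0.0, 0.0, 0.0), (50.0, 0.0, 0.0), (0.0, 55.0, 0.0)],
        sizes=[40, 35, 25],
        sigma=3.0,
        energy_means=[-3.3, -3.0, -1.5],
        seed=11,
    )
    return make_pose_cloud(spec)


class TestClustering:
    def test_single_pose(self):
        [c] = cluster_poses([atom_pose((1.0, 2.0, 3.0), -4.2)])
        assert c.population == 1
        assert c.best_energy == -4.2

    def test_three_cloud_populations_recovered(self, three_cluster_poses):
        clusters = cluster_poses(three_cluster_poses, cutoff=15.0)
        assert sorted(c.population for c in clusters) == [25, 35, 40]

    def test_cluster_properties_against_brute_force(self, three_cluster_poses):
        poses = three_cluster_poses
        clusters = cluster_poses(poses, cutoff=15.0)
        assert sum(c.population for c in clusters) == len(poses)
        all_members = sorted(i for c in clusters for i in c.member_ids)
        assert all_members == list(range(len(poses)))
        centroids = np.array([p.centroid for p in poses])
        for c in clusters:
            # leader is the lowest-energy member and its centroid is stored
            leader = min(c.member_ids, key=lambda i: (poses[i].energy, i))
            assert np.allclose(c.centroid, centroids[leader])
            assert c.best_energy == poses[leader].energy
            # every member lies within the cutoff of its leader (brute force)
            d = np.linalg.norm(centroids[c.member_ids] - centroids[leader], axis=1)
            assert np.all(d <= 15.0)
        # leaders are mutually farther apart than the cutoff
        leaders = [min(c.member_ids, key=lambda i: poses[i].energy) for c in clusters]
        for a in range(len(leaders)):
            for b in range(a):
                # a later leader must be out of range of every earlier leader
                da = np.linalg.norm(centroids[leaders[a]] - centroids[leaders[b]])
                assert da > 15.0

    @pytest.mark.parametrize("separation,expected", [(14.9, 1), (15.1, 2)])
    def test_cutoff_boundary(self, separation, expected):
        poses = [atom_pose((0, 0, 0), -2.0), atom_pose((separation, 0, 0), -1.0)]
        assert len(cluster_poses(poses, cutoff=15.0)) == expected

    def test_input_order_invariance(self, three_cluster_poses):
        poses = three_cluster_poses
        ref = cluster_poses(poses, cutoff=15.0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(poses))
        shuffled = [poses[i] for i in perm]
        out = cluster_poses(shuffled, cutoff=15.0)
        ref_sets = sorted(frozenset(c.member_ids) for c in ref)
        out_sets = sorted(frozenset(int(perm[i]) for i in c.member_ids) for c in out)
        assert ref_sets == out_sets

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_poses([])


class TestPopulationEnergyTable:
    def test_single_cluster_single_row(self):
        clusters = cluster_poses([atom_pose((0, 0, 0), -3.0)])
        table = population_energy_table(clusters)
        assert len(table) == 1
        assert table.loc[0, "population"] == 1

    def test_three_cloud_table(self, three_cluster_poses):
        table = population_energy_table(cluster_poses(three_cluster_poses))
        assert table["population"].sum() == 100
        assert (table["best_energy"].diff().dropna() >= 0).all()


class TestTruePositives:
    def test_dominant_cluster_selected(self, three_cluster_poses):
        clusters = cluster_poses(three_cluster_poses)
        selected = true_positives(clusters, min_population_frac=0.05, energy_margin=1.0)
        populations = {c.population for c in selected}
        # the -1.5 kcal/mol cluster is populous but not competitive in energy
        assert populations == {40, 35}

    def test_low_energy_singleton_rejected(self):
        poses = [atom_pose((i * 40.0, 0, 0), -2.0) for i in range(199)]
        poses.append(atom_pose((0, 0, 1.0), -9.0))
        clusters = cluster_poses(poses)
        selected = true_positives(clusters)
        # singletons far from everything are below the population floor even
        # when they carry the global energy minimum
        assert all(c.population >= 0.05 * 200 for c in selected)

    def test_population_without_energy_is_not_enough(self):
        near = [atom_pose((0, 0, 0), -5.0 + 0.01 * i) for i in range(50)]
        far = [atom_pose((100.0, 0, 0), -2.0 + 0.01 * i) for i in range(50)]
        selected = true_positives(cluster_poses(near + far), energy_margin=1.0)
        assert len(selected) == 1
        assert selected[0].best_energy == pytest.approx(-5.0)


class TestEnergyNormalization:
    @pytest.mark.parametrize("total,n,expected", [
        (-6.0, 3, -2.0),
        (-14.0, 10, -1.4),   # double-helix value per disaccharide unit
        (-3.3, 1, -3.3),
    ])
    def test_arithmetic(self, total, n, expected):
        assert energy_per_disaccharide(total, n) == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(e=st.floats(min_value=-50, max_value=0), c=st.floats(min_value=0.1, max_value=10))
    def test_homogeneous_in_energy(self, e, c):
        assert energy_per_disaccharide(c * e, 3) == pytest.approx(
            c * energy_per_disaccharide(e, 3)
        )

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            energy_per_disaccharide(-6.0, 0)


class TestInteractingDisaccharides:
    def hexamer(self):
        # 3 disaccharides x 2 atoms, strung out along x
        coords = np.array([[5.0 * i, 100.0, 0.0] for i in range(6)])
        return Pose(("C",) * 6, coords, -5.0,
                    disaccharide_map=np.array([1, 1, 2, 2, 3, 3]))

    def test_all_far_counts_zero(self):
        protein = np.array([[0.0, 0.0, 0.0]])
        assert count_interacting_disaccharides(self.hexamer(), protein) == 0

    def test_two_of_three_in_contact(self):
        pose = self.hexamer()
        protein = np.array([
            pose.coords[0] + [0.0, 3.5, 0.0],   # disaccharide 1
            pose.coords[4] + [0.0, 3.5, 0.0],   # disaccharide 3
        ])
        assert count_interacting_disaccharides(pose, protein, cutoff=4.0) == 2

    def test_count_monotone_in_cutoff(self):
        pose = self.hexamer()
        rng = np.random.default_rng(5)
        protein = pose.coords + rng.normal(0, 3.0, pose.coords.shape)
        counts = [
            count_interacting_disaccharides(pose, protein, cutoff=c)
            for c in (8.0, 6.0, 4.0, 2.0, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-20, 20, (40, 3))
        pose = Pose(("C",) * 40, coords, -5.0,
                    disaccharide_map=np.repeat(np.arange(1, 21), 2))
        protein = rng.uniform(-20, 20, (400, 3))
        d = np.linalg.norm(coords[:, None, :] - protein[None, :, :], axis=2)
        want = len(set(pose.disaccharide_map[(d <= 4.0).any(axis=1)]))
        assert count_interacting_disaccharides(pose, protein, cutoff=4.0) == want

    def test_missing_map_rejected(self):
        pose = Pose(("C",), np.zeros((1, 3)), -1.0)
        with pytest.raises(ValueError, match="disaccharide_map"):
            count_interacting_disaccharides(pose, np.zeros((1, 3)))


class TestContactResidues:
    def toy_epitope_structure(self):
        # residues numbered/named exactly as the NAD-groove S-loop epitope
        residues = [
            ("A", 184, "THR", "C", (0.0, 0.0, 0.0)),
            ("A", 186, "LYS", "C", (4.0, 0.0, 0.0)),
            ("A", 191, "PRO", "C", (8.0, 0.0, 0.0)),
            ("A", 192, "SER", "C", (12.0, 0.0, 0.0)),
            ("A", 194, "LYS", "C", (16.0, 0.0, 0.0)),
        ]
        return make_structure(residues)

    def test_single_nearby_residue(self):
        structure = make_structure([
            ("A", 10, "GLY", "C", (0.0, 0.0, 0.0)),
            ("A", 20, "ALA", "C", (50.0, 0.0, 0.0)),
        ])
        report = contact_residues(atom_pose((0.0, 3.0, 0.0)), structure)
        assert report.contact_residues == [("A", 10, "GLY")]

    def test_far_ligand_gives_empty_report(self):
        structure = self.toy_epitope_structure()
        report = contact_residues(atom_pose((0.0, 500.0, 0.0)), structure)
        assert report.contact_residues == []
        assert report.overlap == 0.0
        assert report.matched_epitope is None

    def test_full_epitope_contact_matches_with_unit_overlap(self):
        structure = self.toy_epitope_structure()
        lig = Pose(("C",) * 5,
                   structure.coord + np.array([0.0, 3.0, 0.0]),
                   -3.3, disaccharide_map=np.ones(5, dtype=int))
        report = contact_residues(lig, structure)
        assert report.matched_epitope == "OR-groove S-loop"
        assert report.overlap == 1.0

    def test_hydrogens_ignored(self):
        structure = make_structure([
            ("A", 10, "GLY", "H", (0.0, 0.0, 0.0)),
            ("A", 20, "ALA", "C", (0.0, 0.0, 50.0)),
        ])
        report = contact_residues(atom_pose((0.0, 3.0, 0.0)), structure)
        assert report.contact_residues == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        n = 400
        residues = [
            ("A", i // 4 + 1, "GLY", "C", tuple(rng.uniform(-30, 30, 3)))
            for i in range(n)
        ]
        structure = make_structure(residues)
        lig_coords = rng.uniform(-30, 30, (20, 3))
        lig = Pose(("C",) * 20, lig_coords, -2.0,
                   disaccharide_map=np.ones(20, dtype=int))
        report = contact_residues(lig, structure)
        d = np.linalg.norm(
            structure.coord[:, None, :] - lig_coords[None, :, :], axis=2
        )
        want = sorted({residues[i][1] for i in range(n) if (d[i] <= 4.0).any()})
        assert [r[1] for r in report.contact_residues] == want

    def test_rigid_translation_invariance(self):
        structure = self.toy_epitope_structure()
        lig = Pose(("C",) * 5, structure.coord + np.array([0.0, 3.0, 0.0]), -3.3)
        shift = np.array([12.0, -7.0, 3.0])
        moved_structure = structure.copy()
        moved_structure.coord = structure.coord + shift
        moved_lig = Pose(lig.elements, lig.coords + shift, lig.energy)
        r1 = contact_residues(lig, structure)
        r2 = contact_residues(moved_lig, moved_structure)
        assert r1.contact_residues == r2.contact_residues
        assert r1.overlap == r2.overlap


class TestPoseIO:
    def test_round_trip_multi_model_pdb(self, tmp_path, three_cluster_poses):
        poses = three_cluster_poses[:10]
        pdb = tmp_path / "poses.pdb"
        csv = tmp_path / "poses.csv"
        write_poses(pdb, poses, csv)
        back = read_poses(pdb, csv, residues_per_disaccharide=1)
        assert len(back) == len(poses)
        for a, b in zip(poses, back):
            assert np.allclose(a.coords, b.coords, atol=1e-2)  # PDB precision
            assert a.energy == pytest.approx(b.energy)
        clusters_a = cluster_poses(poses)
        clusters_b = cluster_poses(back)
        assert [c.population for c in clusters_a] == [c.population for c in clusters_b]

    def test_missing_energy_rejected(self, tmp_path, three_cluster_poses):
        import pandas as pd

        pdb = tmp_path / "poses.pdb"
        write_poses(pdb, three_cluster_poses[:5])
        energies = pd.DataFrame({"model": [1, 2, 3], "energy": [-1.0, -2.0, -3.0]})
        with pytest.raises(ValueError, match="model 4"):
            read_poses(pdb, energies)
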
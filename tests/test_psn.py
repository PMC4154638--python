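"""Interaction-strength networks: contact counting, normalization, clusters,
the I_min scan, I_crit detection, hubs and the persistence consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import psncomm as pc


def _two_residue_ensemble(distance):
    """Two ALA residues (2 and 3 side-chain atoms) with all side-chain atoms
    mutually within `distance` of each other across residues."""
    import pandas as pd

    rows, coords = [], []
    for res_index, (x_offset, n_side) in enumerate(((0.0, 2), (distance, 3))):
        base = np.array([x_offset, 0.0, 0.0])
        rows.append((res_index, res_index + 1, "ALA", "CA", "C", False))
        coords.append(base + np.array([0.0, 1.0, 0.0]))
        for k in range(n_side):
            rows.append((res_index, res_index + 1, "ALA", f"CB{k}", "C", False))
            coords.append(base + np.array([0.0, 0.0, 0.01 * k]))
    atoms = pd.DataFrame(
        rows, columns=["res_index", "res_id", "res_name", "atom_name", "element", "is_hydrogen"]
    )
    return pc.Ensemble(coords=np.asarray(coords)[None], atoms=atoms)


class TestCountAtomPairs:
    def test_all_pairs_within_cutoff(self):
        # 2 atoms x 3 atoms all mutually within the cutoff -> 6 distinct pairs
        ens = _two_residue_ensemble(distance=0.3)
        sel = pc.select_atoms(ens, "side-chain-heavy")
        counts = pc.count_atom_pairs(ens, sel, cutoff=0.45, seq_exclusion=1)
        assert counts[0, 0, 1] == 6
        assert counts[0, 1, 0] == 6

    def test_far_apart_zero(self):
        ens = _two_residue_ensemble(distance=5.0)
        sel = pc.select_atoms(ens, "side-chain-heavy")
        counts = pc.count_atom_pairs(ens, sel, cutoff=0.45, seq_exclusion=1)
        assert counts.sum() == 0

    def test_symmetry_and_exclusion_on_random_coordinates(self):
        ref = pc.make_reference_polymer(15, seed=3)
        ens = pc.sample_gaussian_ensemble(
            ref, pc.CovarianceSpec(n_residues=15), 5, seed=3
        )
        sel = pc.select_atoms(ens, "side-chain-heavy")
        counts = pc.count_atom_pairs(ens, sel, cutoff=2.0)
        assert np.array_equal(counts, counts.transpose(0, 2, 1))
        assert np.all(counts.diagonal(axis1=1, axis2=2) == 0)
        for i in range(14):  # sequence neighbours excluded
            assert np.all(counts[:, i, i + 1] == 0)

    def test_brute_force_oracle(self):
        ref = pc.make_reference_polymer(10, seed=7)
        ens = pc.sample_gaussian_ensemble(
            ref, pc.CovarianceSpec(n_residues=10), 3, seed=7
        )
        sel = pc.select_atoms(ens, "side-chain-heavy")
        cutoff = 1.5
        counts = pc.count_atom_pairs(ens, sel, cutoff=cutoff)
        for f in range(3):
            for i in range(10):
                for j in range(10):
                    if abs(i - j) < 2:
                        continue
                    expected = sum(
                        np.linalg.norm(ens.coords[f, a] - ens.coords[f, b]) <= cutoff
                        for a in sel.per_residue[i]
                        for b in sel.per_residue[j]
                    )
                    assert counts[f, i, j] == expected


class TestInteractionStrength:
    def test_hand_arithmetic(self):
        n = np.array([[0, 4], [4, 0]])
        table = pc.NormalizationTable({"ALA": 64.0})
        I = pc.interaction_strength(n, ["ALA", "ALA"], table)
        assert I[0, 1] == pytest.approx(6.25)
        assert I[1, 1] == 0.0

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        n = rng.integers(0, 10, size=(6, 6))
        n = n + n.T
        np.fill_diagonal(n, 0)
        types = ["ALA", "GLY", "LEU", "ALA", "PHE", "GLY"]
        t1 = pc.NormalizationTable({"ALA": 10, "GLY": 5, "LEU": 20, "PHE": 30})
        t2 = pc.NormalizationTable({k: 2 * v for k, v in t1.values.items()})
        assert np.allclose(
            pc.interaction_strength(n, types, t2),
            pc.interaction_strength(n, types, t1) / 2,
        )

    def test_missing_type_raises(self):
        n = np.zeros((2, 2))
        table = pc.NormalizationTable({"ALA": 1.0})
        with pytest.raises(pc.NormalizationError):
            pc.interaction_strength(n, ["ALA", "TRP"], table)


class TestSelfNormalization:
    def test_brute_force_recount(self, replicate_frames):
        ens = replicate_frames(10, 4)
        chain = pc.PlantedChain(residues=(2, 4, 6), persistence=1.0, min_atom_pairs=3)
        planted = pc.plant_contact_chain(ens, chain)
        sel = pc.select_atoms(planted, "side-chain-heavy")
        table = pc.self_normalization(planted, sel, 0.45)
        counts = pc.count_atom_pairs(planted, sel, 0.45).mean(axis=0)
        totals = counts.sum(axis=1)
        expected = {}
        for res, name in enumerate(planted.residue_names):
            expected[name] = max(expected.get(name, 1.0), totals[res], 1.0)
        assert table.values == expected

    def test_isolated_residues_floor(self, ala_polymer):
        ens = ala_polymer(8)
        sel = pc.select_atoms(ens, "side-chain-heavy")
        table = pc.self_normalization(ens, sel, 0.45)
        assert table["ALA"] == 1.0  # no contacts anywhere -> floor

    def test_deterministic(self, replicate_frames):
        ens = replicate_frames(8, 3)
        sel = pc.select_atoms(ens, "side-chain-heavy")
        assert (
            pc.self_normalization(ens, sel).values
            == pc.self_normalization(ens, sel).values
        )


class TestBuildPsn:
    def test_edgeless_graph(self):
        I = np.full((5, 5), 3.0)
        np.fill_diagonal(I, 0)
        g = pc.build_psn(I, i_min=10.0)
        assert g.largest_cluster_size == 0
        assert g.orphans == [0, 1, 2, 3, 4]
        assert g.clusters == []

    def test_components_by_hand(self):
        g = pc.PSNGraph.from_edges(7, [(1, 2), (2, 3), (5, 6)])
        assert g.clusters[0] == {1, 2, 3}
        assert g.clusters[1] == {5, 6}
        assert g.largest_cluster_size == 3
        assert 0 in g.orphans and 4 in g.orphans

    def test_strict_inequality_edge_rule(self):
        I = np.array([[0.0, 7.0], [7.0, 0.0]])
        assert not pc.build_psn(I, i_min=7.0).has_edge(0, 1)
        assert pc.build_psn(I, i_min=6.9).has_edge(0, 1)

    def test_union_find_oracle_on_random_graphs(self, union_find_oracle):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            I = rng.uniform(0, 10, size=(n, n))
            I = (I + I.T) / 2
            np.fill_diagonal(I, 0)
            i_min = float(rng.uniform(2, 8))
            g = pc.build_psn(I, i_min)
            edges = g.edges
            assert g.clusters == union_find_oracle(n, edges)


class TestIminScan:
    def test_step_function(self):
        I = np.full((6, 6), 10.0)
        np.fill_diagonal(I, 0)
        profile = pc.imin_scan(I, 0, 20, 1.0)
        expected = np.where(profile.i_min_values < 10.0, 6, 0)
        assert np.array_equal(profile.sizes, expected)

    def test_monotone_non_increasing_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 20))
            I = rng.uniform(0, 40, size=(n, n))
            I = (I + I.T) / 2
            np.fill_diagonal(I, 0)
            profile = pc.imin_scan(I)
            assert np.all(np.diff(profile.sizes) <= 0)

    def test_profile_matches_independent_recomputation(self):
        rng = np.random.default_rng(9)
        I = rng.uniform(0, 30, size=(10, 10))
        I = (I + I.T) / 2
        np.fill_diagonal(I, 0)
        profile = pc.imin_scan(I, 0, 35, 0.5)
        for x, size in zip(profile.i_min_values, profile.sizes):
            assert pc.build_psn(I, x).largest_cluster_size == size

    def test_default_grid_shape(self):
        I = np.zeros((3, 3))
        profile = pc.imin_scan(I)
        assert len(profile.i_min_values) == 201
        assert profile.i_min_values[0] == 0.0
        assert profile.i_min_values[-1] == pytest.approx(40.0)


class TestDetectIcrit:
    def test_constructed_step(self):
        profile = pc.IminScanProfile(
            [6.6, 6.8, 7.0, 7.2, 7.4], [100, 100, 100, 10, 10], 6.6, 7.4, 0.2
        )
        result = pc.detect_icrit(profile)
        assert result.icrit == pytest.approx(7.2)
        assert result.drop == 90

    def test_tie_broken_toward_smaller_imin(self):
        profile = pc.IminScanProfile(
            [1, 2, 3, 4, 5], [100, 60, 60, 20, 20], 1, 5, 1
        )
        assert pc.detect_icrit(profile).icrit == 2

    def test_flat_profile_raises(self):
        profile = pc.IminScanProfile([1, 2, 3], [50, 50, 50], 1, 3, 1)
        with pytest.raises(pc.NoTransitionError):
            pc.detect_icrit(profile)

    def test_two_scale_network_from_planted_contacts(self, replicate_frames):
        # three 4-residue blocks strongly connected inside (I = 20), bridged
        # by weaker links (I = 5.5): the detected transition separates the
        # two planted strength scales
        ens = replicate_frames(24, 100)
        chains = [
            pc.PlantedChain((0, 2, 4, 6), min_atom_pairs=4, persistence=0.8, rng_seed=1),
            pc.PlantedChain((8, 10, 12, 14), min_atom_pairs=4, persistence=0.8, rng_seed=2),
            pc.PlantedChain((16, 18, 20, 22), min_atom_pairs=4, persistence=0.8, rng_seed=3),
            pc.PlantedChain((6, 8), min_atom_pairs=2, persistence=0.44, rng_seed=4),
            pc.PlantedChain((14, 16), min_atom_pairs=2, persistence=0.44, rng_seed=5),
        ]
        for chain in chains:
            ens = pc.plant_contact_chain(ens, chain)
        sel = pc.select_atoms(ens, "side-chain-heavy")
        mean_n = pc.count_atom_pairs(ens, sel, 0.45).mean(axis=0)
        table = pc.NormalizationTable.uniform(16.0, ens.residue_names)
        I = pc.interaction_strength(mean_n, ens.residue_names, table)
        assert I[0, 2] == pytest.approx(20.0)
        assert I[6, 8] == pytest.approx(5.5)
        result = pc.detect_icrit(pc.imin_scan(I))
        assert 5.5 < result.icrit < 20.0


class TestHubs:
    def test_star_graph(self):
        g = pc.PSNGraph.from_edges(6, [(0, k) for k in range(1, 6)])
        hub_list, profile = pc.hubs(g, min_degree=4)
        assert hub_list == [(0, 5)]
        assert profile == {0: 5, 1: 1, 2: 1, 3: 1, 4: 1, 5: 1}

    def test_edgeless(self):
        g = pc.PSNGraph.from_edges(4, [])
        hub_list, profile = pc.hubs(g)
        assert hub_list == []
        assert set(profile.values()) == {0}

    def test_degree_oracle_random(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            edges = {
                tuple(sorted((int(a), int(b))))
                for a, b in rng.integers(0, n, size=(n * 2, 2))
                if a != b
            }
            g = pc.PSNGraph.from_edges(n, sorted(edges))
            _, profile = pc.hubs(g)
            for node in range(n):
                assert profile[node] == sum(node in e for e in edges)


class TestConsensus:
    def _per_frame(self, present_frames, total=100, n=4, edge=(0, 2)):
        I = np.zeros((total, n, n))
        for f in range(present_frames):
            I[f, edge[0], edge[1]] = I[f, edge[1], edge[0]] = 10.0
        return I

    def test_edge_kept_at_060(self):
        graph, persistence = pc.consensus_psn(self._per_frame(60), i_min=7.0)
        assert graph.has_edge(0, 2)
        assert persistence[0, 2] == pytest.approx(0.60)

    def test_edge_dropped_at_049(self):
        graph, persistence = pc.consensus_psn(self._per_frame(49), i_min=7.0)
        assert not graph.has_edge(0, 2)
        assert persistence[0, 2] == pytest.approx(0.49)

    def test_boundary_inclusive(self):
        graph, _ = pc.consensus_psn(self._per_frame(50), i_min=7.0)
        assert graph.has_edge(0, 2)

    def test_planted_chain_kept_and_dropped(self, replicate_frames):
        for persistence, expected in ((0.6, True), (0.4, False)):
            ens = replicate_frames(10, 50)
            chain = pc.PlantedChain(residues=(2, 5, 8), persistence=persistence, rng_seed=4)
            planted = pc.plant_contact_chain(ens, chain)
            sel = pc.select_atoms(planted, "side-chain-heavy")
            counts = pc.count_atom_pairs(planted, sel, 0.45)
            table = pc.NormalizationTable.uniform(10.0, planted.residue_names)
            per_frame_I = pc.interaction_strength(counts, planted.residue_names, table)
            graph, _ = pc.consensus_psn(per_frame_I, i_min=7.0)
            assert graph.has_edge(2, 5) is expected
            assert graph.has_edge(5, 8) is expected

    @given(st.integers(0, 100))
    @settings(deadline=None, max_examples=20)
    def test_edge_set_monotone_in_threshold(self, present):
        per_frame = self._per_frame(present)
        edges_by_threshold = []
        for thr in (0.25, 0.5, 0.75):
            graph, _ = pc.consensus_psn(per_frame, i_min=7.0, persistence_threshold=thr)
            edges_by_threshold.append(set(graph.edges))
        assert edges_by_threshold[0] >= edges_by_threshold[1] >= edges_by_threshold[2]


def test_interaction_strength_rotation_invariant():
    ref = pc.make_reference_polymer(12, seed=2)
    ens = pc.sample_gaussian_ensemble(ref, pc.CovarianceSpec(n_residues=12), 5, seed=2)
    chain = pc.PlantedChain(residues=(3, 6, 9), persistence=1.0, rng_seed=0)
    ens = pc.plant_contact_chain(ens, chain)
    sel = pc.select_atoms(ens, "side-chain-heavy")
    table = pc.NormalizationTable.uniform(8.0, ens.residue_names)
    I_orig = pc.interaction_strength(
        pc.count_atom_pairs(ens, sel, 0.45), ens.residue_names, table
    )
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
    rotated = pc.Ensemble(
        coords=ens.coords @ rot.T + np.array([1.0, -2.0, 3.0]),
        atoms=ens.atoms,
        frames_per_window=ens.frames_per_window,
    )
    I_rot = pc.interaction_strength(
        pc.count_atom_pairs(rotated, sel, 0.45), rotated.residue_names, table
    )
    assert np.allclose(I_orig, I_rot, atol=1e-6)
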
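"""Gyration tensor, PBC unwrapping, clustering, contacts per monomer."""

import numpy as np
import pytest

from bilayerlab.core import MoleculeDef, Topology, Trajectory
from bilayerlab.polymer import (cluster_polymers, contacts_per_monomer,
                                gyration, make_whole)
from bilayerlab.synth import BilayerSpec, gen_bilayer, gen_polymer

from conftest import brute_single_linkage, frame_of


def chain_topology(chain_lengths, species="PE"):
    molecules, cursor = [], 0
    for n in chain_lengths:
        idx = tuple(range(cursor, cursor + n))
        molecules.append(MoleculeDef(species, idx,
                                     tuple(f"C{j+1}" for j in range(n))))
        cursor += n
    k = len(chain_lengths)
    return Topology(tuple(molecules), (species,) * k, (None,) * k, ((),) * k, cursor)


class TestGyration:
    def test_two_unit_mass_beads(self):
        res = gyration(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert res.r_g == pytest.approx(0.5)
        assert res.eigenvalues == pytest.approx((0.25, 0.0, 0.0))

    def test_straight_rod_closed_form(self):
        # N equally spaced unit masses, spacing a: R_g^2 = (N^2-1)/12 * a^2
        for n in (4, 7, 10):
            rod = np.column_stack([np.arange(n) * 1.0, np.zeros(n), np.zeros(n)])
            assert gyration(rod).r_g ** 2 == pytest.approx((n * n - 1) / 12.0)

    def test_trace_equals_mean_square_distance_from_com(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(20, 3))
        masses = rng.uniform(0.5, 2.0, 20)
        res = gyration(coords, masses)
        w = masses / masses.sum()
        com = w @ coords
        msd_com = float(np.sum(w * np.sum((coords - com) ** 2, axis=1)))
        assert res.r_g ** 2 == pytest.approx(msd_com, rel=1e-12)
        assert sum(res.eigenvalues) == pytest.approx(res.r_g ** 2, rel=1e-10)

    def test_invariant_under_rotation_and_translation(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(15, 3))
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 1.0])
        a, b = gyration(coords), gyration(moved)
        assert a.r_g == pytest.approx(b.r_g, rel=1e-10)
        assert a.eigenvalues == pytest.approx(b.eigenvalues, rel=1e-8, abs=1e-12)

    def test_single_bead_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = gyration(np.array([[1.0, 2.0, 3.0]]))
        assert res.r_g == 0.0


class TestMakeWhole:
    def test_identity_when_not_crossing_boundary(self):
        coords = np.array([[1.0, 1, 1], [1.4, 1, 1], [1.8, 1, 1]])
        box = np.array([10.0, 10, 10])
        np.testing.assert_array_equal(make_whole(coords, box), coords)

    def test_bond_across_boundary_restored(self):
        coords = np.array([[9.8, 1.0, 1.0], [0.2, 1.0, 1.0]])
        box = np.array([10.0, 10, 10])
        whole = make_whole(coords, box)
        assert np.linalg.norm(whole[1] - whole[0]) == pytest.approx(0.4)

    def test_wrapped_chain_recovers_true_bond_lengths(self):
        rng = np.random.default_rng(6)
        steps = rng.normal(scale=0.3, size=(30, 3))
        true = np.cumsum(steps, axis=0)
        box = np.array([5.0, 5.0, 5.0])
        wrapped = np.mod(true, box)
        whole = make_whole(wrapped, box)
        np.testing.assert_allclose(np.diff(whole, axis=0), np.diff(true, axis=0),
                                   atol=1e-12)

    def test_molecule_spanning_half_box_rejected(self):
        coords = np.column_stack([np.arange(0, 6.0, 0.4), np.zeros(15), np.zeros(15)])
        with pytest.raises(ValueError, match="half the box"):
            make_whole(coords, np.array([8.0, 8.0, 8.0]))


class TestClusterPolymers:
    def test_separated_chains_are_two_clusters(self):
        topo = chain_topology([2, 2])
        frame = frame_of([[1, 1, 5], [1.4, 1, 5], [5, 5, 5], [5.4, 5, 5]])
        res = cluster_polymers(frame, topo, 0.8)
        assert res.n_clusters == 2
        assert res.largest_cluster_fraction == 0.5

    def test_transitive_linkage(self):
        # A touches B, B touches C, A far from C -> one cluster
        topo = chain_topology([1, 1, 1])
        frame = frame_of([[1.0, 1, 5], [1.7, 1, 5], [2.4, 1, 5]])
        res = cluster_polymers(frame, topo, 0.8)
        assert res.n_clusters == 1

    def test_deterministic_labels_by_lowest_molecule_index(self):
        topo = chain_topology([1, 1, 1])
        frame = frame_of([[1.0, 1, 5], [8.0, 1, 5], [1.5, 1, 5]])
        res = cluster_polymers(frame, topo, 0.8)
        assert res.membership[0] == 0 and res.membership[2] == 0
        assert res.membership[1] == 1

    def test_invalid_cutoff_rejected(self):
        topo = chain_topology([1])
        with pytest.raises(ValueError):
            cluster_polymers(frame_of([[1, 1, 1]]), topo, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        n_chains = int(rng.integers(5, 20))
        lengths = rng.integers(2, 8, n_chains).tolist()
        topo = chain_topology(lengths)
        box = rng.uniform(4.0, 7.0, 3)
        coords = rng.uniform(0, box, (sum(lengths), 3))
        frame = frame_of(coords, box=box)
        cutoff = float(rng.uniform(0.4, 1.2))
        res = cluster_polymers(frame, topo, cutoff)
        per_mol = []
        cursor = 0
        for n in lengths:
            per_mol.append(coords[cursor:cursor + n])
            cursor += n
        expected = brute_single_linkage(per_mol, box, cutoff)
        assert [res.membership[i] for i in range(n_chains)] == expected

    def test_generator_modes_give_known_cluster_counts(self):
        mem, _ = gen_bilayer(BilayerSpec(n_dppc=400, n_dlipc=0, n_chol=0, seed=1))
        for seed in (0, 1, 2):
            agg, _ = gen_polymer(5, 15, "aggregated", mem, seed=seed)
            assert cluster_polymers(agg.frames[0], agg.topology, 0.8).n_clusters == 1
            disp, _ = gen_polymer(4, 15, "dispersed", mem, seed=seed)
            assert cluster_polymers(disp.frames[0], disp.topology, 0.8).n_clusters == 4

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(10)
        topo = chain_topology([3] * 10)
        box = np.array([6.0, 6.0, 6.0])
        frame = frame_of(rng.uniform(0, 6, (30, 3)), box=box)
        counts = [cluster_polymers(frame, topo, c).n_clusters
                  for c in (0.3, 0.6, 0.9, 1.2, 1.5)]
        assert counts == sorted(counts, reverse=True)


class TestContactsPerMonomer:
    def test_isolated_chains_give_zero(self):
        topo = chain_topology([2, 2])
        frame = frame_of([[1, 1, 5], [1.4, 1, 5], [5, 5, 5], [5.4, 5, 5]])
        traj = Trajectory(topo, [frame])
        assert contacts_per_monomer(traj, cutoff=0.5) == 0.0

    def test_two_monomer_convention(self):
        # one inter-chain pair shared by two monomers: 2*1/2 = 1.0 per monomer
        topo = chain_topology([1, 1])
        frame = frame_of([[1.0, 1, 5], [1.4, 1, 5]])
        traj = Trajectory(topo, [frame])
        assert contacts_per_monomer(traj, cutoff=0.5) == 1.0

    def test_intra_chain_pairs_excluded(self):
        topo = chain_topology([3])
        frame = frame_of([[1.0, 1, 5], [1.3, 1, 5], [1.6, 1, 5]])
        traj = Trajectory(topo, [frame])
        assert contacts_per_monomer(traj, cutoff=0.5) == 0.0

    def test_monomers_per_bead_rescaling(self):
        topo = chain_topology([1, 1])
        frame = frame_of([[1.0, 1, 5], [1.4, 1, 5]])
        traj = Trajectory(topo, [frame])
        assert contacts_per_monomer(traj, cutoff=0.5, monomers_per_bead=2.0) == 0.5

    def test_random_aggregate_matches_brute_force(self):
        rng = np.random.default_rng(3)
        lengths = [5, 6, 4]
        topo = chain_topology(lengths)
        box = np.array([5.0, 5.0, 5.0])
        coords = 2.0 + rng.uniform(0, 1.5, (sum(lengths), 3))
        traj = Trajectory(topo, [frame_of(coords, box=box)])
        got = contacts_per_monomer(traj, cutoff=0.8)
        owners = np.concatenate([np.full(n, k) for k, n in enumerate(lengths)])
        pairs = 0
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if owners[i] != owners[j]:
                    from conftest import brute_min_image
                    if brute_min_image(coords[i], coords[j], box) < 0.8:
                        pairs += 1
        assert got == pytest.approx(2.0 * pairs / len(coords))
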
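"""MSD/diffusion, order parameter, 1D profiles, 2D maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from bilayerlab.core import Frame, MoleculeDef, Topology, Trajectory
from bilayerlab.fields import (MSDResult, fit_diffusion, map2d, msd,
                               order_parameter, profile_1d, second_legendre,
                               unwrap_lateral)
from bilayerlab.synth import (BilayerSpec, gen_bilayer, gen_buckled_bilayer,
                              gen_ordered_chains, gen_random_walk)

from conftest import frame_of


def tracer_trajectory(positions, box=(10.0, 10.0, 5.0), dt=1.0):
    """Trajectory of free single-bead tracers; positions (n_frames, n, 3)."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[1]
    molecules = tuple(MoleculeDef("TRACER", (i,), ("T1",)) for i in range(n))
    topo = Topology(molecules, ("TRACER",) * n, (None,) * n, ((),) * n, n)
    frames = [Frame(time=k * dt, coordinates=positions[k],
                    box=np.asarray(box, dtype=float))
              for k in range(positions.shape[0])]
    return Trajectory(topo, frames)


class TestMSD:
    def test_static_particles_give_zero(self):
        pos = np.tile(np.array([[[1.0, 2.0, 2.5], [4.0, 4.0, 2.5]]]), (10, 1, 1))
        traj = tracer_trajectory(pos)
        r = msd(traj, np.arange(2), max_lag=5)
        np.testing.assert_array_equal(r.values, np.zeros(6))

    def test_ballistic_particle_closed_form_and_com_contract(self):
        # single particle moving at constant velocity v: msd = v^2 t^2 without
        # drift removal; exactly 0 with it (the particle IS the COM)
        v = 0.1
        pos = np.array([[[v * k, 0.0, 2.5]] for k in range(20)])
        traj = tracer_trajectory(pos)
        r = msd(traj, np.arange(1), max_lag=8, remove_com_drift=False)
        np.testing.assert_allclose(r.values, (v * r.lag_times) ** 2, atol=1e-12)
        r0 = msd(traj, np.arange(1), max_lag=8, remove_com_drift=True)
        np.testing.assert_allclose(r0.values, 0.0, atol=1e-12)

    def test_unwrapping_recovers_ground_truth_tracks(self):
        traj, truth = gen_random_walk(16, 2e-3, 100.0, 200, (6, 6, 4), seed=4)
        tracks = unwrap_lateral(traj, np.arange(16))
        # unwrapping is exact up to a common offset fixed by frame 0
        np.testing.assert_allclose(tracks, truth["unwrapped"], atol=1e-9)

    def test_matches_4dt_within_three_standard_errors(self):
        D = 1e-3
        traj, _ = gen_random_walk(256, D, 100.0, 1000, (50, 50, 10), seed=1)
        r = msd(traj, np.arange(256), max_lag=100, origin_stride=10)
        for lag in (10, 50, 100):
            t = r.lag_times[lag]
            # independent-sample SE estimate; generous but principled
            se = 4 * D * t * np.sqrt(2.0 / (256 * max(r.n_origins[lag] // lag, 1)))
            assert abs(r.values[lag] - 4 * D * t) < 3 * se + 1e-9

    def test_max_lag_beyond_span_rejected(self):
        traj, _ = gen_random_walk(4, 1e-3, 100.0, 10, (5, 5, 5), seed=0)
        with pytest.raises(ValueError):
            msd(traj, np.arange(4), max_lag=10)


class TestFitDiffusion:
    def test_exact_linear_msd(self):
        t = np.arange(0.0, 11.0)
        result = MSDResult(lag_times=t, values=4 * 0.5 * t, n_origins=np.ones(11, int))
        d, se = fit_diffusion(result)
        assert d == pytest.approx(0.5, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_data_rejected(self):
        t = np.arange(0.0, 11.0)
        result = MSDResult(lag_times=t, values=t, n_origins=np.ones(11, int))
        with pytest.raises(ValueError):
            fit_diffusion(result, window=(100.0, 200.0))

    def test_recovery_within_five_percent(self):
        traj, _ = gen_random_walk(256, 1e-3, 100.0, 4000, (50, 50, 10), seed=2)
        r = msd(traj, np.arange(256), max_lag=400, origin_stride=10)
        d, _ = fit_diffusion(r)
        assert d == pytest.approx(1e-3, rel=0.05)

    def test_static_input_returns_exactly_zero(self):
        traj, _ = gen_random_walk(16, 0.0, 100.0, 50, (10, 10, 5), seed=0)
        r = msd(traj, np.arange(16), max_lag=10)
        d, _ = fit_diffusion(r)
        assert d == 0.0

    def test_free_intercept_variant(self):
        t = np.arange(0.0, 11.0)
        result = MSDResult(lag_times=t, values=np.where(t > 0, 4 * 0.5 * t + 1.0, 0.0),
                           n_origins=np.ones(11, int))
        d, _ = fit_diffusion(result, zero_intercept=False)
        assert d == pytest.approx(0.5, rel=1e-9)


class TestOrderParameter:
    def _bond_traj(self, vectors):
        """One 2-bead lipid per bond vector, heads stacked on a fake bilayer."""
        n = len(vectors)
        molecules, heads, acyl = [], [], []
        coords = np.zeros((2 * n, 3))
        for i, v in enumerate(vectors):
            molecules.append(MoleculeDef("DPPC", (2 * i, 2 * i + 1), ("PO4", "C1A")))
            heads.append(2 * i)
            acyl.append(((2 * i, 2 * i + 1),))
            coords[2 * i] = [5.0, 5.0, 5.0]
            coords[2 * i + 1] = coords[2 * i] + v
        topo = Topology(tuple(molecules), ("DPPC",) * n, tuple(heads), tuple(acyl),
                        2 * n)
        return Trajectory(topo, [frame_of(coords, box=(100, 100, 100))])

    def test_bonds_along_normal_give_one(self):
        traj = self._bond_traj([[0, 0, 0.4]] * 5)
        p, _ = order_parameter(traj)
        assert p == pytest.approx(1.0)

    def test_in_plane_bonds_give_minus_half(self):
        traj = self._bond_traj([[0.4, 0, 0], [0, 0.4, 0]] * 3)
        p, _ = order_parameter(traj)
        assert p == pytest.approx(-0.5)

    def test_recovers_target_order(self):
        vectors = 0.4 * gen_ordered_chains(0.5, 2000, seed=7)
        traj = self._bond_traj(vectors)
        p, per_bond = order_parameter(traj)
        assert per_bond.size == 2000
        assert p == pytest.approx(second_legendre(vectors).mean(), abs=1e-9)

    def test_no_bonds_rejected(self):
        traj, _ = gen_random_walk(3, 0.0, 1.0, 2, (5, 5, 5), seed=0)
        with pytest.raises(ValueError):
            order_parameter(traj, species={"TRACER"})

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-1, 1), min_size=15, max_size=15))
    def test_bounds_never_violated(self, flat):
        v = np.array(flat).reshape(5, 3)
        v = v[np.linalg.norm(v, axis=1) > 1e-3]
        if v.size == 0:
            return
        p2 = second_legendre(v)
        assert np.all(p2 >= -0.5 - 1e-12) and np.all(p2 <= 1.0 + 1e-12)


class TestProfile1D:
    def test_density_peaks_at_leaflet_positions(self):
        traj, _ = gen_bilayer(BilayerSpec(n_dppc=100, n_dlipc=0, n_chol=0,
                                          jitter=0.0, seed=0))
        topo = traj.topology
        heads = np.array([topo.head_bead_of_molecule[i]
                          for i in range(topo.n_molecules)])
        p = profile_1d(traj, heads, "density", bin_width=0.3)
        occupied = p.bin_centers[p.values > 0]
        # heads sit at +-separation/2 = +-2.0 from the membrane center
        assert len(occupied) == 2
        np.testing.assert_allclose(np.sort(occupied), [-2.0, 2.0], atol=0.16)

    def test_density_integral_conserves_bead_count(self):
        traj, _ = gen_bilayer(BilayerSpec(n_dppc=50, n_dlipc=50, n_chol=20, seed=3))
        all_beads = np.arange(traj.topology.bead_count)
        p = profile_1d(traj, all_beads, "density", bin_width=0.25)
        total = np.nansum(p.values) * 0.25 * traj.frames[0].area
        assert total == pytest.approx(traj.topology.bead_count, rel=1e-9)

    def test_symmetric_system_gives_symmetric_profile(self):
        traj, _ = gen_bilayer(BilayerSpec(n_dppc=200, n_dlipc=0, n_chol=0,
                                          jitter=0.0, seed=1))
        all_beads = np.arange(traj.topology.bead_count)
        # bin width chosen so bead planes fall inside bins, not on edges
        p = profile_1d(traj, all_beads, "density", bin_width=0.3)
        vals = np.nan_to_num(p.values)
        np.testing.assert_allclose(vals, vals[::-1], atol=1e-9)

    def test_order_profile_localizes_acyl_bonds(self):
        traj, _ = gen_bilayer(BilayerSpec(n_dppc=60, n_dlipc=0, n_chol=0,
                                          jitter=0.0, seed=0))
        p = profile_1d(traj, np.arange(0), "order", bin_width=0.2)
        finite = ~np.isnan(p.values)
        # synthetic chains are vertical stacks: p = 1 wherever bonds exist
        assert finite.any()
        np.testing.assert_allclose(p.values[finite], 1.0, atol=1e-12)
        assert np.all(np.abs(p.bin_centers[finite]) < 2.0)  # inside the core

    def test_zero_bin_width_rejected(self, flat_bilayer):
        with pytest.raises(ValueError):
            profile_1d(flat_bilayer, np.arange(8), "density", bin_width=0.0)


class TestMap2D:
    def test_flat_bilayer_thickness_constant(self, flat_bilayer):
        m = map2d(flat_bilayer, "thickness", n_bins=2)
        occupied = ~np.isnan(m.grid)
        assert occupied.any()
        np.testing.assert_allclose(m.grid[occupied], 4.0, atol=1e-12)

    def test_buckled_bilayer_thickness_matches_generator_field(self):
        # the generator offsets leaflets along z by the nominal thickness, so
        # without jitter the per-cell head separation is exact even on the
        # curved profile
        traj, truth = gen_buckled_bilayer(strain=0.1, L=20.0, Ly=8.0, jitter=0.0)
        m = map2d(traj, "thickness", n_bins=8)
        occupied = ~np.isnan(m.grid)
        assert occupied.any()
        np.testing.assert_allclose(m.grid[occupied], truth["thickness"], atol=1e-9)
        # with jitter, deviations stay at the jitter-noise scale for most
        # cells (cell-edge crossings on steep slopes cause the tail)
        traj2, truth2 = gen_buckled_bilayer(strain=0.1, L=20.0, Ly=8.0,
                                            jitter=0.02, seed=5)
        m2 = map2d(traj2, "thickness", n_bins=8)
        dev = np.abs(m2.grid[~np.isnan(m2.grid)] - truth2["thickness"])
        assert np.median(dev) < 0.05

    def test_uniform_density_flat_within_poisson_noise(self):
        rng = np.random.default_rng(9)
        n = 40_000
        coords = rng.uniform(0, 10, (n, 3))
        molecules = tuple(MoleculeDef("TRACER", (i,), ("T1",)) for i in range(n))
        topo = Topology(molecules, ("TRACER",) * n, (None,) * n, ((),) * n, n)
        traj = Trajectory(topo, [frame_of(coords, box=(10, 10, 10))])
        m = map2d(traj, "density", n_bins=10)
        counts = m.occupancy.ravel()
        expected = n / 100.0
        stat = np.sum((counts - expected) ** 2 / expected)
        # chi-square goodness of fit at the 1% level, 99 dof
        assert stat < chi2.ppf(0.99, 99)

    def test_density_normalization_conserves_bead_count(self):
        traj, _ = gen_bilayer(BilayerSpec(n_dppc=80, n_dlipc=40, n_chol=10, seed=2))
        m = map2d(traj, "density", n_bins=5)
        cell_area = traj.frames[0].area / 25.0
        assert np.nansum(m.grid) * cell_area == pytest.approx(
            traj.topology.bead_count, rel=1e-9)

    def test_recentering_keeps_moving_cluster_stationary(self):
        # a compact cluster drifting across the box: recentered density maps
        # from the two halves of the trajectory peak in the same cell
        rng = np.random.default_rng(3)
        n_beads, n_frames = 60, 12
        base = rng.normal(scale=0.6, size=(n_beads, 3))
        molecules = (MoleculeDef("PE", tuple(range(n_beads)),
                                 tuple(f"C{i+1}" for i in range(n_beads))),)
        topo = Topology(molecules, ("PE",), (None,), ((),), n_beads)
        frames = []
        for k in range(n_frames):
            drift = np.array([0.9 * k, 0.4 * k, 0.0])
            coords = np.mod(base + drift + 5.0, 10.0)
            frames.append(frame_of(coords, box=(10, 10, 10), time=float(k)))
        traj = Trajectory(topo, frames)
        peaks = []
        for half in (frames[:6], frames[6:]):
            sub = Trajectory(topo, [frame_of(f.coordinates, f.box, t)
                                    for t, f in enumerate(half)])
            m = map2d(sub, "density", n_bins=10, center_on=np.array([0]))
            peaks.append(np.unravel_index(np.nanargmax(m.grid), m.grid.shape))
        assert peaks[0] == peaks[1]

    def test_thickness_with_empty_cells_masked_not_error(self, flat_bilayer):
        m = map2d(flat_bilayer, "thickness", n_bins=50)
        assert np.isnan(m.grid).any()  # sparse system: most cells unoccupied

    def test_invalid_grid_rejected(self, flat_bilayer):
        with pytest.raises(ValueError):
            map2d(flat_bilayer, "density", n_bins=1)
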
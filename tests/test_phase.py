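"""Phase analytics on hand-built and analytic fixtures."""

import numpy as np
import pytest

from actophase.errors import SinglePhaseError
from actophase.phase import (
    DensityProfile,
    bootstrap_width,
    coexistence_densities,
    directional_profiles,
    interfacial_width,
    largest_cluster,
    partition_fractions,
    phase_velocities,
    radial_density_profile,
)
from actophase.sim import SimulationParameters, SystemState, TrajectoryDump

BOX = (40.0, 40.0, 60.0)


def _state(positions, beads_per_chain=5, active=None):
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    n_chains = (n + beads_per_chain - 1) // beads_per_chain
    chain_id = np.repeat(np.arange(n_chains), beads_per_chain)[:n]
    head = np.zeros(n, dtype=bool)
    head[np.searchsorted(chain_id, np.arange(n_chains))] = True
    act = np.ones(n_chains, dtype=bool) if active is None else np.asarray(active)
    return SystemState(pos, np.zeros_like(pos), chain_id, head, act)


def _blob(rng, center, n_chains, beads_per_chain=5, spread=1.0):
    pts = rng.normal(scale=spread, size=(n_chains * beads_per_chain, 3))
    return pts + np.asarray(center)


def _brute_force_components(pos, cutoff, box):
    """Union-find over all pairs — the independent clustering oracle."""
    n = len(pos)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    b = np.asarray(box)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= b * np.round(d / b)
            if np.dot(d, d) <= cutoff ** 2:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    roots = [find(i) for i in range(n)]
    comps = {}
    for i, r in enumerate(roots):
        comps.setdefault(r, []).append(i)
    return sorted(comps.values(), key=len, reverse=True)


class TestLargestCluster:
    def test_two_blobs_larger_one_wins_vs_bruteforce(self, rng):
        big = _blob(rng, (-8.0, 0, 0), 10)
        small = _blob(rng, (8.0, 0, 0), 5)
        state = _state(np.vstack([big, small]))
        res = largest_cluster(state, cutoff=1.5, box=BOX)
        oracle = _brute_force_components(state.positions, 1.5, BOX)
        assert set(res.bead_indices) >= set(oracle[0])
        assert set(res.chain_ids) == set(range(10))
        assert res.com[0] == pytest.approx(-8.0, abs=1.0)

    def test_all_linked_single_cluster(self):
        pos = np.column_stack([np.arange(20) * 1.0 - 10.0,
                               np.zeros(20), np.zeros(20)])
        state = _state(pos)
        res = largest_cluster(state, cutoff=1.5, box=BOX)
        assert len(res.chain_ids) == state.n_chains

    def test_isolated_chain_com_is_centroid(self):
        pos = np.array([[1.0, 2.0, 3.0], [1.9, 2.0, 3.0], [1.0, 2.8, 3.0],
                        [0.5, 2.0, 3.5], [1.2, 2.2, 2.6]])
        state = _state(pos, beads_per_chain=5)
        res = largest_cluster(state, cutoff=1.5, box=BOX)
        # circular-mean COM carries a tiny curvature bias on the torus
        np.testing.assert_allclose(res.com, pos.mean(axis=0), atol=1e-2)

    def test_empty_state_raises(self):
        state = _state(np.zeros((1, 3)))
        state.positions = np.zeros((0, 3))
        state.chain_id = np.zeros(0, dtype=int)
        with pytest.raises(ValueError):
            largest_cluster(state, box=BOX)

    def test_periodic_wraparound_linkage(self):
        # beads straddling the x boundary belong to one cluster
        pos = np.array([[-19.9, 0, 0], [19.9, 0, 0], [19.2, 0, 0],
                        [-19.2, 0, 0], [18.5, 0, 0]])
        state = _state(pos, beads_per_chain=5)
        res = largest_cluster(state, cutoff=1.5, box=BOX)
        assert len(res.bead_indices) == 5
        # COM sits near the boundary, not near x = 0
        assert abs(abs(res.com[0]) - 20.0) < 1.5


class TestRadialProfile:
    def test_manual_shell_arithmetic(self, rng):
        # 100 beads uniformly in the shell r in [2, 3]
        u = rng.normal(size=(100, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        radii = (rng.random(100) * (27 - 8) + 8) ** (1 / 3)
        state = _state(u * radii[:, None])
        prof = radial_density_profile(state, np.zeros(3), bin_width=1.0, box=BOX)
        expected = 100.0 / (4.0 / 3.0 * np.pi * (27 - 8))
        assert prof.rho[2] == pytest.approx(expected, rel=1e-9)
        assert prof.rho[0] == prof.rho[1] == 0.0

    def test_ideal_gas_flat_profile(self, rng):
        n = 20000
        rho0 = n / np.prod(BOX)
        state = _state((rng.random((n, 3)) - 0.5) * np.array(BOX))
        prof = radial_density_profile(state, np.zeros(3), 0.5, BOX)
        sel = prof.counts > 0
        stderr = np.sqrt(prof.counts[sel]) / (prof.counts[sel] / prof.rho[sel])
        assert np.all(np.abs(prof.rho[sel] - rho0) < 3.5 * stderr + 1e-12)

    def test_mass_conservation(self, rng):
        state = _state(rng.normal(scale=3.0, size=(500, 3)))
        prof = radial_density_profile(state, np.zeros(3), 0.5, BOX)
        assert prof.counts.sum() == 500

    def test_bin_width_validation(self, rng):
        state = _state(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            radial_density_profile(state, np.zeros(3), bin_width=25.0, box=BOX)


class TestDirectionalProfiles:
    def test_isotropic_sphere_profiles_agree(self, rng):
        u = rng.normal(size=(20000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pos = u * (8.0 * rng.random(20000) ** (1 / 3))[:, None]
        perp, par = directional_profiles(_state(pos), np.zeros(3), 1.0, 1.0, BOX)
        sel = slice(0, 7)  # interior bins with good statistics
        # agreement within combined Poisson sampling error
        se = np.sqrt(perp.counts[sel] / perp.counts[sel].clip(1) ** 2
                     * perp.rho[sel] ** 2
                     + par.counts[sel] / par.counts[sel].clip(1) ** 2
                     * par.rho[sel] ** 2)
        assert np.all(np.abs(perp.rho[sel] - par.rho[sel]) < 4.0 * se)

    def test_beads_outside_slab_give_empty_profile(self):
        pos = np.tile([[0.0, 0.0, 20.0]], (50, 1))
        with pytest.warns(UserWarning, match="perpendicular"):
            perp, _ = directional_profiles(_state(pos), np.zeros(3), 1.0, 0.5, BOX)
        assert perp.counts.sum() == 0

    def test_mass_conservation_in_pencils(self, rng):
        pos = rng.normal(scale=2.0, size=(400, 3))
        perp, par = directional_profiles(_state(pos), np.zeros(3), 1.0, 0.5, BOX)
        in_z_pencil = (np.abs(pos[:, 0]) <= 1.0) & (np.abs(pos[:, 1]) <= 1.0)
        assert par.counts.sum() == in_z_pencil.sum()
        in_x = (np.abs(pos[:, 1]) <= 1.0) & (np.abs(pos[:, 2]) <= 1.0)
        in_y = (np.abs(pos[:, 0]) <= 1.0) & (np.abs(pos[:, 2]) <= 1.0)
        assert perp.counts.sum() == in_x.sum() + in_y.sum()


def tanh_profile(rho_den=0.6, rho_sat=0.01, r0=10.0, w=2.0, rmax=30.0, dr=0.5):
    edges = np.arange(0, rmax + dr, dr)
    r = 0.5 * (edges[:-1] + edges[1:])
    rho = rho_sat + 0.5 * (rho_den - rho_sat) * (1 - np.tanh((r - r0) / w))
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return DensityProfile("isotropic", r, rho, rho * vol, dr, volumes=vol)


class TestCoexistenceDensities:
    def test_step_profile_exact(self):
        edges = np.arange(0, 10.5, 0.25)
        r = 0.5 * (edges[:-1] + edges[1:])
        rho = np.interp(r, [0, 5, 8, 10], [0.6, 0.6, 0.01, 0.01])
        co = coexistence_densities(DensityProfile("isotropic", r, rho, rho, 0.25))
        assert co.two_phase
        assert co.rho_den == pytest.approx(0.6, rel=1e-9)
        assert co.rho_sat == pytest.approx(0.01, rel=1e-9)

    def test_tanh_profile_recovery(self):
        co = coexistence_densities(tanh_profile())
        assert co.two_phase
        assert co.rho_den == pytest.approx(0.6, rel=0.02)
        assert co.rho_sat == pytest.approx(0.01, rel=0.05)

    def test_uniform_profile_single_phase(self):
        r = np.arange(0.25, 10, 0.5)
        rho = np.full_like(r, 0.05)
        co = coexistence_densities(DensityProfile("isotropic", r, rho, rho, 0.5))
        assert not co.two_phase
        assert co.rho_den == pytest.approx(0.05)

    def test_too_few_bins_raises(self):
        r = np.arange(0.25, 3, 0.5)
        with pytest.raises(ValueError):
            coexistence_densities(
                DensityProfile("isotropic", r, np.ones_like(r), r, 0.5))


class TestInterfacialWidth:
    def test_linear_ramp_width_within_resolution(self):
        edges = np.arange(0, 10.5, 0.25)
        r = 0.5 * (edges[:-1] + edges[1:])
        rho = np.interp(r, [0, 4, 6, 10], [0.6, 0.6, 0.01, 0.01])
        w = interfacial_width(DensityProfile("isotropic", r, rho, rho, 0.25))
        assert w == pytest.approx(2.0, abs=2 * 0.25)

    def test_tanh_width_ordering_and_ratio(self):
        w1 = interfacial_width(tanh_profile(w=2.0))
        w2 = interfacial_width(tanh_profile(w=4.0))
        assert w2 > w1
        assert w2 / w1 == pytest.approx(2.0, rel=0.15)

    def test_sharp_step_bounded_by_bins(self):
        r = np.arange(0.25, 15, 0.5)
        rho = np.where(r < 7, 0.6, 0.01)
        w = interfacial_width(DensityProfile("isotropic", r, rho, rho, 0.5),
                              smooth_bins=1)
        assert w <= 2 * 0.5 + 1e-12

    def test_single_phase_raises(self):
        r = np.arange(0.25, 10, 0.5)
        rho = np.full_like(r, 0.05)
        with pytest.raises(SinglePhaseError):
            interfacial_width(DensityProfile("isotropic", r, rho, rho, 0.5))


class TestBootstrapWidth:
    def test_smooth_profile_small_spread(self):
        bw = bootstrap_width(tanh_profile(), n_trials=1000, rng=3)
        assert bw.n_ok + bw.n_skipped == 1000
        assert bw.sd < 0.05 * bw.mean

    def test_seeded_determinism(self):
        a = bootstrap_width(tanh_profile(), n_trials=200, rng=7)
        b = bootstrap_width(tanh_profile(), n_trials=200, rng=7)
        assert (a.mean, a.sd) == (b.mean, b.sd)


def _drift_dump(n_snapshots=3, drift=(0.0, 0.0, 5.0), dump_every=20_000):
    """Dense blob + far dilute chains, all drifting rigidly per snapshot."""
    rng = np.random.default_rng(1)
    dense = _blob(rng, (0, 0, 0), 8, beads_per_chain=5, spread=1.2)
    dilute = np.array([[15.0, 15.0, 20.0 + 3 * k, ] for k in range(10)])
    pos0 = np.vstack([dense, dilute])
    params = SimulationParameters(
        n_chains=10, beads_per_chain=5, box=BOX, total_steps=dump_every * 8,
        dump_every=dump_every, analysis_start=0, bias_steps=0)
    dump = TrajectoryDump(params=params)
    for k in range(n_snapshots):
        st = _state(pos0 + np.asarray(drift) * k)
        st.step = k * dump_every
        dump.append(st)
    return dump


class TestPhaseVelocities:
    def test_static_configuration_zero(self):
        dump = _drift_dump(drift=(0, 0, 0))
        v = phase_velocities(dump, analysis_only=False)
        assert v.dense == 0.0 and v.dilute == 0.0

    def test_uniform_drift_arithmetic(self):
        # 5 sigma per snapshot at snapshot spacing 2e4 * 0.01 tau = tau'
        dump = _drift_dump(drift=(0.0, 0.0, 5.0))
        v = phase_velocities(dump, analysis_only=False)
        assert v.dense == pytest.approx(5.0, rel=1e-9)
        assert v.dilute == pytest.approx(5.0, rel=1e-9)

    def test_single_snapshot_raises(self):
        dump = _drift_dump(n_snapshots=1)
        with pytest.raises(ValueError):
            phase_velocities(dump, analysis_only=False)


class TestPartitionFractions:
    def test_hand_built_counts(self, rng):
        # 15 chains: 10 active, 5 passive; 3 active + 1 passive in the blob
        bpc = 5
        blob_chains = [0, 1, 2, 10]      # chains placed inside the cluster
        pos = np.zeros((15 * bpc, 3))
        far = iter(np.linspace(8, 64, 15))
        for c in range(15):
            if c in blob_chains:
                base = np.array([0.0, 0.0, 0.0])
            else:
                d = next(far)
                base = np.array([10.0 + d % 18, 15.0 - d % 7, -20.0 + d % 9])
            pos[c * bpc:(c + 1) * bpc] = base + 0.3 * rng.normal(size=(bpc, 3))
        active = np.array([True] * 10 + [False] * 5)
        state = _state(pos, beads_per_chain=bpc, active=active)
        cluster = largest_cluster(state, cutoff=1.5, box=BOX)
        assert set(cluster.chain_ids) == set(blob_chains)
        pf = partition_fractions(state, cluster)
        assert pf.active_over_total == pytest.approx(3 / 15)
        assert pf.passive_over_class == pytest.approx(1 / 5)
        assert pf.active_over_class == pytest.approx(3 / 10)

    def test_all_chains_in_cluster(self, rng):
        pos = _blob(rng, (0, 0, 0), 10, beads_per_chain=5, spread=1.0)
        active = np.array([True] * 8 + [False] * 2)
        state = _state(pos, beads_per_chain=5, active=active)
        cluster = largest_cluster(state, cutoff=1.5, box=BOX)
        pf = partition_fractions(state, cluster)
        assert pf.active_over_total == pytest.approx(0.8)
        assert pf.passive_over_class == pytest.approx(1.0)

    def test_no_passive_chains_nan(self, rng):
        pos = _blob(rng, (0, 0, 0), 4, beads_per_chain=5)
        state = _state(pos, beads_per_chain=5)
        cluster = largest_cluster(state, cutoff=1.5, box=BOX)
        pf = partition_fractions(state, cluster)
        assert np.isnan(pf.passive_over_class)
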
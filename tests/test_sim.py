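"""Langevin engine: potentials, forces, integrator and protocol contracts."""

import numpy as np
import pytest

from actophase.errors import BondOverstretchError, SingularOverlapError
from actophase.sim import (
    SimulationParameters,
    SystemState,
    fene_energy,
    fene_force,
    initialize_condensed,
    langevin_step,
    lj_energy,
    run_simulation,
    total_energy,
    total_forces,
)

P = SimulationParameters(n_chains=1, beads_per_chain=2, box=(20.0, 20.0, 20.0),
                         total_steps=10, dump_every=10, bias_steps=0,
                         analysis_start=0)


def _gas_state(n, box, rng, spacing=None):
    """Non-interacting monomer gas (each bead its own chain)."""
    if spacing is None:
        pos = (rng.random((n, 3)) - 0.5) * (np.asarray(box) - 3.0)
    else:
        side = int(np.ceil(n ** (1 / 3)))
        g = np.mgrid[0:side, 0:side, 0:side].reshape(3, -1).T[:n] * spacing
        pos = g - g.mean(axis=0)
    return SystemState(pos, rng.normal(size=(n, 3)), np.arange(n),
                       np.ones(n, dtype=bool), np.ones(n, dtype=bool))


def _chain_state(n_chains, bpc, rng, box, f_passive=0.0):
    pos = np.empty((n_chains * bpc, 3))
    for c in range(n_chains):
        start = (rng.random(3) - 0.5) * (np.asarray(box) / 2)
        pos[c * bpc] = start
        for b in range(1, bpc):
            step = rng.normal(size=3)
            pos[c * bpc + b] = pos[c * bpc + b - 1] + 0.97 * step / np.linalg.norm(step)
    cid = np.repeat(np.arange(n_chains), bpc)
    head = np.zeros(n_chains * bpc, dtype=bool)
    head[::bpc] = True
    active = np.ones(n_chains, dtype=bool)
    n_passive = int(round(f_passive * n_chains))
    if n_passive:
        active[n_chains - n_passive:] = False
    return SystemState(pos, rng.normal(size=pos.shape), cid, head, active)


class TestPotentials:
    def test_fene_at_zero_extension(self):
        assert fene_energy(0.0, P) == 0.0

    def test_fene_diverges_at_r0(self):
        assert fene_energy(1.4999, P) > fene_energy(1.49, P) > fene_energy(1.0, P)
        with pytest.raises(BondOverstretchError):
            fene_energy(1.5, P)

    def test_fene_reference_value(self):
        # -0.5 * (100 * 0.40) * 1.5^2 * ln(1 - (1/1.5)^2) = 26.450 kBT
        assert fene_energy(1.0, P) == pytest.approx(26.4504, abs=2e-4)

    def test_fene_force_is_negative_gradient(self):
        h = 1e-7
        for r in (0.3, 0.8, 1.2):
            num = (fene_energy(r + h, P) - fene_energy(r - h, P)) / (2 * h)
            assert fene_force(r, P) == pytest.approx(num, rel=1e-5)

    def test_lj_zero_at_sigma(self):
        assert lj_energy(1.0, P) == pytest.approx(0.0, abs=1e-15)

    def test_lj_minimum(self):
        assert lj_energy(2 ** (1 / 6), P) == pytest.approx(-0.40, rel=1e-12)

    def test_lj_at_cutoff_reference_value(self):
        # 1.6 * (2.5^-12 - 2.5^-6) = -6.527e-3 kBT
        assert lj_energy(2.4999999, P) == pytest.approx(-6.527e-3, rel=1e-3)
        assert lj_energy(2.5, P) == 0.0  # truncated

    def test_lj_shift_variant_vanishes_at_cutoff(self):
        ps = P.replace(lj_shift=True)
        assert lj_energy(2.4999999, ps) == pytest.approx(0.0, abs=1e-8)
        assert lj_energy(2 ** (1 / 6), ps) == pytest.approx(
            -0.40 - lj_energy(2.4999999, P), rel=1e-3)

    def test_lj_singular_overlap(self):
        with pytest.raises(SingularOverlapError):
            lj_energy(0.0, P)


class TestForces:
    def test_two_beads_at_sigma_repulsion_free(self, rng):
        # |F| = 24 eps / sigma = 9.6 kBT/sigma along the separation axis
        state = _gas_state(2, (20, 20, 20), rng)
        state.positions[:] = [[0, 0, 0], [1.0, 0, 0]]
        F = total_forces(state, P.replace(n_chains=2, beads_per_chain=1))
        assert F[0, 0] == pytest.approx(-9.6)
        assert F[1, 0] == pytest.approx(9.6)
        np.testing.assert_allclose(F[:, 1:], 0.0, atol=1e-12)

    def test_active_head_bead_force(self, rng):
        params = SimulationParameters(
            n_chains=2, beads_per_chain=1, box=(20.0, 20.0, 20.0), f_act=2.0,
            f_passive=0.5, total_steps=10, dump_every=10, bias_steps=0,
            analysis_start=0)
        state = _gas_state(2, (20, 20, 20), rng)
        state.positions[:] = [[-5.0, 0, 0], [5.0, 0, 0]]
        state.active_chain[:] = [True, False]
        F = total_forces(state, params)
        np.testing.assert_allclose(F[0], [0.0, 0.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(F[1], [0.0, 0.0, 0.0], atol=1e-12)

    def test_newtons_third_law(self, rng):
        state = _chain_state(6, 8, rng, (14.0, 14.0, 14.0))
        params = SimulationParameters(
            n_chains=6, beads_per_chain=8, box=(14.0, 14.0, 14.0),
            total_steps=10, dump_every=10, bias_steps=0, analysis_start=0)
        # relax random-walk overlaps so force magnitudes are physical
        langevin_step(state, params, seed=12, n_steps=2_000, fcap=50.0, vcap=2.0)
        F = total_forces(state, params)
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-9)

    def test_cell_list_matches_all_pairs_reference(self, rng):
        for trial in range(5):
            state = _chain_state(8, 10, rng, (18.0, 18.0, 24.0))
            params = SimulationParameters(
                n_chains=8, beads_per_chain=10, box=(18.0, 18.0, 24.0),
                total_steps=10, dump_every=10, bias_steps=0, analysis_start=0)
            F_cells = total_forces(state, params)
            F_ref = total_forces(state, params, all_pairs=True)
            np.testing.assert_allclose(F_cells, F_ref, atol=1e-10)

    def test_overstretched_bond_raises(self, rng):
        state = _gas_state(2, (20, 20, 20), rng)
        state.chain_id = np.zeros(2, dtype=int)
        state.active_chain = np.ones(1, dtype=bool)
        state.head[:] = [True, False]
        state.positions[:] = [[0, 0, 0], [1.6, 0, 0]]
        with pytest.raises(BondOverstretchError):
            total_forces(state, P)


class TestIntegrator:
    def test_free_streaming(self):
        # zero force, gamma = 0: displacement = v * dt each step
        state = SystemState(np.zeros((1, 3)), np.array([[0.5, -0.2, 1.0]]),
                            np.zeros(1, int), np.ones(1, bool), np.ones(1, bool))
        params = P.replace(n_chains=1, beads_per_chain=1)
        langevin_step(state, params, seed=1, n_steps=100, gamma=0.0)
        np.testing.assert_allclose(
            state.positions[0], np.array([0.5, -0.2, 1.0]) * 0.01 * 100,
            rtol=1e-12)

    def test_equipartition_free_beads(self, rng):
        # Langevin thermostat drives a dilute gas to kBT = 1 within 2%
        n = 125
        state = _gas_state(n, (40, 40, 40), rng, spacing=3.0)
        params = SimulationParameters(
            n_chains=n, beads_per_chain=1, box=(40.0, 40.0, 40.0),
            total_steps=10, dump_every=10, bias_steps=0, analysis_start=0)
        langevin_step(state, params, seed=3, n_steps=5_000)  # equilibrate
        v2_mean = langevin_step(state, params, seed=4, n_steps=100_000)
        T_kin = v2_mean / (3 * n)
        assert T_kin == pytest.approx(1.0, abs=0.02)

    def test_nve_energy_conservation(self, rng):
        # gamma = 0, no noise: velocity-Verlet conserves energy.  The probe
        # is a cold LJ monomer cluster: its softest-mode frequency gives
        # dt * omega ~ 0.05, so the measured drift isolates the integrator
        # (the FENE+WCA bond is ~30x stiffer and would dominate otherwise;
        # its force/gradient consistency is tested separately).
        state = _gas_state(13, (16.0, 16.0, 16.0), rng, spacing=1.15)
        params = SimulationParameters(
            n_chains=13, beads_per_chain=1, box=(16.0, 16.0, 16.0),
            lj_shift=True, lj_cutoff=4.0, total_steps=10, dump_every=10,
            bias_steps=0, analysis_start=0)
        langevin_step(state, params, seed=50, n_steps=3_000, fcap=50.0, vcap=2.0)
        langevin_step(state, params, seed=51, n_steps=5_000, kT=0.05)
        langevin_step(state, params, seed=5, n_steps=100, gamma=0.0)
        # window-average the energy to sample across the shadow oscillation
        e0 = []
        for _ in range(10):
            langevin_step(state, params, seed=0, n_steps=10, gamma=0.0)
            e0.append(total_energy(state, params))
        e1 = []
        for _ in range(20):
            langevin_step(state, params, seed=0, n_steps=500, gamma=0.0)
            e1.append(total_energy(state, params))
        drift = abs(np.mean(e1[-5:]) - np.mean(e0)) / state.n_beads
        assert drift < 1e-4

    def test_active_chain_terminal_drift(self, rng):
        # overdamped mobility: v_COM -> F_act / (n_beads * gamma)
        bpc, f_act = 25, 5.0
        params = SimulationParameters(
            n_chains=1, beads_per_chain=bpc, box=(40.0, 40.0, 40.0),
            f_act=f_act, total_steps=10, dump_every=10, bias_steps=0,
            analysis_start=0)
        state = _chain_state(1, bpc, rng, params.box)
        langevin_step(state, params, seed=70, n_steps=2_000, fcap=50.0, vcap=2.0)
        langevin_step(state, params, seed=7, n_steps=20_000)  # reach terminal
        unwrapped = np.zeros(bpc)
        prev = state.positions[:, 2].copy()
        # short chunks keep per-chunk drift well under the half-box, so the
        # minimum-image unwrapping is unambiguous
        n_chunks, chunk = 400, 2_000
        for c in range(n_chunks):
            langevin_step(state, params, seed=100 + c, n_steps=chunk)
            dz = state.positions[:, 2] - prev
            dz -= 40.0 * np.round(dz / 40.0)
            unwrapped += dz
            prev = state.positions[:, 2].copy()
        v_com = unwrapped.mean() / (n_chunks * chunk * params.dt)
        v_expected = f_act / (bpc * params.gamma)
        assert v_com == pytest.approx(v_expected, rel=0.05)


class TestProtocol:
    def test_zero_production_steps_dumps_initial_state_only(self, rng):
        params = SimulationParameters(
            n_chains=2, beads_per_chain=5, box=(12.0, 12.0, 12.0),
            bias_steps=2_000, total_steps=0, dump_every=100, seed=3,
            analysis_start=0)
        dump = run_simulation(params, cluster_check=False)
        assert len(dump) == 1 and dump.steps == [0]

    def test_snapshot_count_arithmetic(self, rng):
        params = SimulationParameters(
            n_chains=2, beads_per_chain=5, box=(12.0, 12.0, 12.0),
            bias_steps=2_000, total_steps=1_000, dump_every=200, seed=3,
            analysis_start=0)
        dump = run_simulation(params, cluster_check=False)
        # steps 0, 200, ..., 1000 -> 6 snapshots
        assert dump.steps == [0, 200, 400, 600, 800, 1000]

    def test_deterministic_given_seed(self):
        params = SimulationParameters(
            n_chains=3, beads_per_chain=5, box=(12.0, 12.0, 12.0),
            bias_steps=1_000, total_steps=2_000, dump_every=500, seed=11,
            analysis_start=0)
        a = run_simulation(params, cluster_check=False)
        b = run_simulation(params, cluster_check=False)
        for sa, sb in zip(a.snapshots, b.snapshots):
            np.testing.assert_array_equal(sa.positions, sb.positions)
            np.testing.assert_array_equal(sa.velocities, sb.velocities)

    def test_bond_safety_through_a_run(self):
        params = SimulationParameters(
            n_chains=4, beads_per_chain=8, box=(14.0, 14.0, 14.0),
            bias_steps=2_000, total_steps=5_000, dump_every=1_000, seed=2,
            analysis_start=0)
        dump = run_simulation(params, cluster_check=False)
        for s in dump.snapshots:
            d = np.diff(s.positions, axis=0)
            d -= np.asarray(params.box) * np.round(d / np.asarray(params.box))
            same = np.diff(s.chain_id) == 0
            bonds = np.linalg.norm(d[same], axis=1)
            assert bonds.max() < params.fene_R0

    def test_single_chain_initialization_near_center(self):
        params = SimulationParameters(
            n_chains=1, beads_per_chain=25, box=(20.0, 20.0, 20.0),
            bias_steps=30_000, total_steps=10, dump_every=10, seed=8,
            analysis_start=0)
        state = initialize_condensed(params)
        assert np.linalg.norm(state.positions.mean(axis=0)) < 4.0

    def test_passive_labels_fixed_and_seed_independent(self):
        for seed in (1, 2):
            params = SimulationParameters(
                n_chains=10, beads_per_chain=3, box=(14.0, 14.0, 14.0),
                f_passive=0.3, bias_steps=500, total_steps=10, dump_every=10,
                seed=seed, analysis_start=0)
            state = initialize_condensed(params, cluster_check=False)
            np.testing.assert_array_equal(
                state.active_chain, [True] * 7 + [False] * 3)
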
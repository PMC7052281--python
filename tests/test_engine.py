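"""DPD engine: forces, integrator, thermostat and conservation laws."""
from __future__ import annotations

import numpy as np
import pytest

from dpdgel import builder, engine, fixtures
from dpdgel.errors import (ConfigurationError, DegenerateBondError,
                           InstabilityError)
from dpdgel.state import AAM, WATER, BeadSystem, ForceField


def _two_beads(r, box=10.0, v=None, bonds=(), species=(WATER, WATER)):
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    vel = np.zeros((2, 3)) if v is None else np.asarray(v, dtype=float)
    return BeadSystem(positions=pos, velocities=vel,
                      species=np.array(species), box=np.full(3, box),
                      bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2))


def _ff(**kw):
    base = dict(a=np.full((3, 3), 37.5), gamma=4.5, sigma=3.0, kT=1.0,
                dt=0.01)
    base.update(kw)
    return ForceField(**base)


class TestWeightFunction:
    @pytest.mark.parametrize("r,r_cut,expected", [
        (0.0, 1.0, 1.0),        # contact limit
        (1.2, 1.0, 0.0),        # beyond cutoff
        (0.5, 1.0, 0.5),        # piecewise-linear interior
        (1.0, 1.0, 0.0),        # continuous at the cutoff
        (1.0, 2.0, 0.5),
    ])
    def test_values(self, r, r_cut, expected):
        assert engine.weight_function(r, r_cut) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            engine.weight_function(-0.1, 1.0)

    def test_bounded_and_nonincreasing(self):
        r = np.linspace(0, 2, 101)
        w = engine.weight_function(r, 1.0)
        assert np.all((w >= 0) & (w <= 1))
        assert np.all(np.diff(w) <= 1e-15)


class TestPairForces:
    def test_conservative_magnitude_at_half_cutoff(self):
        system = _two_beads(0.5)
        forces, _ = engine.pair_forces(system, _ff(sigma=0.0))
        # a*w = 37.5 * 0.5, repulsive along the pair axis
        assert forces[1, 0] == pytest.approx(18.75)
        assert forces[0, 0] == pytest.approx(-18.75)
        assert np.allclose(forces[:, 1:], 0.0)

    def test_dissipative_term(self):
        system = _two_beads(0.5, v=[[0.0, 0, 0], [-1.0, 0, 0]])
        f_static, _ = engine.pair_forces(_two_beads(0.5), _ff(sigma=0.0))
        f_moving, _ = engine.pair_forces(system, _ff(sigma=0.0))
        # beads approaching: dissipative force opposes closing velocity
        # -gamma * w^2 * (rhat . v_ij) with rhat.v_ij = -1 on bead 1
        assert f_moving[1, 0] - f_static[1, 0] == pytest.approx(4.5 * 0.25)

    def test_beyond_cutoff_exactly_zero(self):
        system = _two_beads(1.2)
        rng = np.random.default_rng(0)
        forces, virial = engine.pair_forces(system, _ff(), rng=rng)
        assert np.all(forces == 0.0) and np.all(virial == 0.0)

    def test_momentum_free_by_antisymmetry(self):
        system = fixtures.pure_water(64, seed=1)
        rng = np.random.default_rng(1)
        forces, _ = engine.pair_forces(system, _ff(), rng=rng)
        assert np.abs(forces.sum(axis=0)).max() < 1e-11

    def test_random_force_needs_rng(self):
        with pytest.raises(ConfigurationError):
            engine.pair_forces(_two_beads(0.5), _ff())

    def test_conservative_force_is_potential_gradient(self):
        """F^C must equal -grad of a_ij R_c/2 (1 - r/R_c)^2 summed over pairs."""
        rng = np.random.default_rng(3)
        system = fixtures.pure_water(20, seed=3)
        ff = _ff(gamma=0.0, sigma=0.0)

        def potential(flat):
            pos = flat.reshape(-1, 3)
            d = pos[:, None] - pos[None]
            d -= system.box * np.round(d / system.box)
            r = np.linalg.norm(d, axis=2)
            iu = np.triu_indices(len(pos), 1)
            rr = r[iu]
            w = np.where(rr < ff.r_cut, 1.0 - rr / ff.r_cut, 0.0)
            return float(np.sum(37.5 * ff.r_cut / 2.0 * w**2))

        forces, _ = engine.pair_forces(system, ff)
        flat = system.positions.ravel().copy()
        h = 1e-6
        idx = rng.choice(flat.size, size=10, replace=False)
        for k in idx:
            fp = flat.copy()
            fm = flat.copy()
            fp[k] += h
            fm[k] -= h
            grad = (potential(fp) - potential(fm)) / (2 * h)
            assert -grad == pytest.approx(forces.ravel()[k], rel=1e-6,
                                          abs=1e-8)


class TestBondForce:
    def test_zero_at_equilibrium_length(self):
        system = _two_beads(1.0, bonds=[(0, 1)], species=(AAM, AAM))
        forces, _ = engine.bond_force(system, _ff(bond_C=4.0))
        assert np.allclose(forces, 0.0)

    @pytest.mark.parametrize("r,C,expected", [
        (1.01, 4.0, 0.04),
        (1.001, 116_000.0, 116.0),
    ])
    def test_restoring_magnitude(self, r, C, expected):
        system = _two_beads(r, bonds=[(0, 1)], species=(AAM, AAM))
        forces, _ = engine.bond_force(system, _ff(bond_C=C))
        # stretched bond pulls bead 1 back toward bead 0
        assert forces[1, 0] == pytest.approx(-expected)
        assert forces[0, 0] == pytest.approx(expected)

    def test_degenerate_bond_raises(self):
        system = _two_beads(0.0, bonds=[(0, 1)], species=(AAM, AAM))
        with pytest.raises(DegenerateBondError):
            engine.bond_force(system, _ff(bond_C=4.0))


class TestCellListAgainstAllPairs:
    """The production cell-list kernel must match the reference O(N^2) path."""

    @pytest.mark.parametrize("n,with_bonds", [(64, False), (200, True)])
    def test_forces_and_virial_match(self, n, with_bonds):
        system = fixtures.pure_water(n, seed=5)
        if with_bonds:
            bonds = [(i, i + 1) for i in range(0, n - 1, 7)]
            system.species[np.array(bonds).ravel()] = AAM
            system.add_bonds(bonds)
        rng = np.random.default_rng(5)
        system.velocities = rng.normal(size=(n, 3))
        ff = _ff(sigma=0.0, bond_C=4.0)
        f_ref, w_ref = engine.pair_forces(system, ff)
        fb, wb = engine.bond_force(system, ff)
        f_kernel, w_kernel = engine.compute_forces(system, ff, random=False)
        assert np.allclose(f_kernel, f_ref + fb, rtol=1e-12, atol=1e-10)
        assert np.allclose(w_kernel, w_ref + wb, rtol=1e-12, atol=1e-10)


class TestIntegration:
    def test_free_flight(self):
        system = _two_beads(3.0, v=[[0.1, 0.2, -0.3], [0, 0, 0]])
        ff = _ff(a=np.zeros((3, 3)), gamma=0.0, sigma=0.0)
        x0 = system.unwrapped.copy()
        engine.advance(system, ff, 10, seed_value=0)
        assert np.allclose(system.unwrapped - x0,
                           10 * ff.dt * system.velocities, atol=1e-14)

    def test_zero_steps_is_identity(self, ff_water):
        system = fixtures.pure_water(32, seed=2)
        snap = system.positions.copy()
        engine.run_nvt(system, ff_water, 0, target_kT=1.0, seed_value=2)
        assert np.array_equal(system.positions, snap)

    def test_momentum_conserved_over_run(self, ff_water):
        system = fixtures.pure_water(128, seed=4)
        p0 = engine.total_momentum(system)
        engine.advance(system, ff_water, 1000, seed_value=4)
        drift = np.abs(engine.total_momentum(system) - p0).max()
        assert drift / system.n_beads < 1e-8

    def test_seeded_determinism(self, ff_water):
        runs = []
        for _ in range(2):
            system = fixtures.pure_water(64, seed=9)
            engine.advance(system, ff_water, 200, seed_value=9)
            runs.append((system.positions.copy(), system.velocities.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_unseeded_stream_rejected(self, ff_water):
        system = fixtures.pure_water(16, seed=0)
        engine._SEEDED = False
        with pytest.raises(ConfigurationError):
            engine.advance(system, ff_water, 1)

    def test_instability_reported_with_step(self):
        system = _two_beads(0.5, v=[[500.0, 0, 0], [0, 0, 0]], box=4.0)
        ff = _ff(a=np.zeros((3, 3)), gamma=0.0, sigma=0.0)
        with pytest.raises(InstabilityError):
            engine.advance(system, ff, 5, seed_value=0)

    def test_thermostat_contract_checked(self, ff_water):
        system = fixtures.pure_water(16, seed=0)
        with pytest.raises(ConfigurationError):
            engine.run_nvt(system, ff_water, 1, target_kT=5.0, seed_value=0)


class TestKineticTemperature:
    def test_at_rest(self):
        system = _two_beads(1.0)
        assert engine.kinetic_temperature(system) == 0.0

    def test_single_configuration_value(self):
        # |v|^2 = 3 for every bead with zero total momentum
        n = 10
        vel = np.zeros((n, 3))
        vel[: n // 2] = [1.0, 1.0, 1.0]
        vel[n // 2:] = [-1.0, -1.0, -1.0]
        system = BeadSystem(positions=np.random.default_rng(0).uniform(0, 5, (n, 3)),
                            velocities=vel,
                            species=np.zeros(n, dtype=np.int64),
                            box=np.full(3, 5.0))
        assert engine.kinetic_temperature(system) == pytest.approx(n / (n - 1))

    def test_maxwell_estimate(self):
        rng = np.random.default_rng(12)
        n = 20000
        system = BeadSystem(positions=rng.uniform(0, 30, (n, 3)),
                            velocities=builder.maxwell_velocities(n, 1.0, rng),
                            species=np.zeros(n, dtype=np.int64),
                            box=np.full(3, 30.0))
        assert engine.kinetic_temperature(system) == pytest.approx(1.0, rel=0.03)


def test_thermostat_holds_target_temperature(ff_water):
    """Fluctuation-dissipation pair keeps kinetic T within 5% of target."""
    system = fixtures.pure_water(300, seed=21)
    engine.advance(system, ff_water, 1500, seed_value=21)  # settle
    traj = engine.run_nvt(system, ff_water, 6000, target_kT=1.0,
                          sample_every=200)
    assert traj.mean_kinetic_T == pytest.approx(1.0, rel=0.05)
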
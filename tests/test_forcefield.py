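"""Energetics and integrator checks against closed forms and oracles."""

import math

import numpy as np
import pytest

from linkedrings import ChannelSpec, Conformation, ModelParams
from linkedrings.catalog import catalog_conformation
from linkedrings.dynamics import maxwell_velocities, simulate
from linkedrings.errors import OverstretchedBondError, WallViolationError
from linkedrings.forcefield import (bending_energy, fene_bond_energy,
                                    kinetic_temperature,
                                    pair_repulsion_energy, total_energy,
                                    total_forces, wall_energy)
from linkedrings.params import StretchProtocol


class TestPairRepulsion:
    def test_zero_at_cutoff(self):
        p = ModelParams()
        assert pair_repulsion_energy(2 ** (1 / 6) * p.sigma, p) == 0.0
        assert pair_repulsion_energy(2.0, p) == 0.0

    def test_epsilon_at_sigma(self):
        p = ModelParams()
        assert pair_repulsion_energy(p.sigma, p) == pytest.approx(p.epsilon)

    def test_matches_direct_formula(self):
        p = ModelParams()
        r = 1.05
        expected = 4 * p.epsilon * ((p.sigma / r) ** 12 - (p.sigma / r) ** 6) \
            + p.epsilon
        assert pair_repulsion_energy(r, p) == pytest.approx(expected, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pair_repulsion_energy(0.0)


class TestFeneBond:
    def test_zero_at_origin(self):
        assert fene_bond_energy(0.0) == 0.0

    def test_diverges_near_maximum(self):
        p = ModelParams()
        e6 = fene_bond_energy((1 - 1e-6) * p.fene_r0, p)
        e12 = fene_bond_energy((1 - 1e-12) * p.fene_r0, p)
        assert e12 > e6 > fene_bond_energy(0.9 * p.fene_r0, p)
        assert e12 > 800.0  # logarithmic divergence towards r0

    def test_overstretch_error(self):
        p = ModelParams()
        with pytest.raises(OverstretchedBondError):
            fene_bond_energy(p.fene_r0, p)

    def test_matches_direct_formula(self):
        p = ModelParams(fene_k=30.0, fene_r0=1.5)
        r = 0.9
        expected = -0.5 * 30.0 * 1.5 ** 2 * math.log(1 - (r / 1.5) ** 2)
        assert fene_bond_energy(r, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing(self):
        p = ModelParams()
        rs = np.linspace(0.1, 1.4, 30)
        es = [fene_bond_energy(r, p) for r in rs]
        assert np.all(np.diff(es) > 0)


class TestBending:
    def _three_beads(self, positions):
        return Conformation(np.asarray(positions, dtype=float),
                            np.ones(len(positions), dtype=np.int64),
                            closed=False)

    def test_straight_triplet_zero(self):
        conf = self._three_beads([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert bending_energy(conf) == pytest.approx(0.0, abs=1e-12)

    def test_hairpin_contributes_two_kappa(self):
        p = ModelParams()
        conf = self._three_beads([[0, 0, 0], [1, 0, 0], [0, 1e-8, 0]])
        assert bending_energy(conf, p) == pytest.approx(2 * p.kappa, rel=1e-6)

    def test_degenerate_bond_raises(self):
        conf = self._three_beads([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            bending_energy(conf)


class TestWall:
    def test_zero_on_axis(self):
        chan = ChannelSpec(diameter=12.0, period_x=100.0)
        assert wall_energy(np.zeros(3), chan) == 0.0

    def test_zero_in_bulk(self):
        assert wall_energy(np.array([0.0, 50.0, 50.0]), ChannelSpec.bulk()) == 0.0

    def test_repulsive_near_wall(self):
        p = ModelParams()
        chan = ChannelSpec(diameter=12.0, period_x=100.0)
        rho = (chan.diameter - p.sigma) / 2 - 0.5 * p.sigma  # gap = sigma
        e = wall_energy(np.array([0.0, rho, 0.0]), chan, p)
        gap = chan.diameter / 2 - rho
        expected = 4 * p.epsilon * ((p.sigma / gap) ** 12 - (p.sigma / gap) ** 6) \
            + p.epsilon
        assert e == pytest.approx(expected, rel=1e-12)
        assert e > 0

    def test_outside_raises(self):
        chan = ChannelSpec(diameter=12.0, period_x=100.0)
        with pytest.raises(WallViolationError):
            wall_energy(np.array([0.0, 6.5, 0.0]), chan)


class TestForces:
    def test_beyond_cutoffs_no_mutual_force(self):
        p = ModelParams()
        conf = Conformation(np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                            np.array([1, 2]), closed=False)
        f = total_forces(conf, p, ChannelSpec.bulk())
        assert np.allclose(f, 0.0)

    def test_pulling_net_force_zero(self, hopf40):
        p = ModelParams(N=40)
        prot = StretchProtocol(force_magnitude=20.0)
        conf = hopf40.copy()
        chan = ChannelSpec.bulk()
        f_with = total_forces(conf, p, chan, protocol=prot)
        f_without = total_forces(conf, p, chan)
        ext = f_with - f_without
        assert np.abs(ext).max() == pytest.approx(20.0)
        assert np.allclose(ext.sum(axis=0), 0.0, atol=1e-9)

    def test_matches_finite_difference_gradient(self, rng):
        p = ModelParams(N=12)
        conf = catalog_conformation("2_1^2", 12)
        conf.positions += 0.02 * rng.standard_normal(conf.positions.shape)
        chan = ChannelSpec(diameter=10.0, period_x=60.0)
        f = total_forces(conf, p, chan)
        h = 1e-6
        for i in range(0, conf.n_beads, 3):
            for d in range(3):
                c = conf.copy()
                c.positions[i, d] += h
                e1 = total_energy(c, p, chan)
                c.positions[i, d] -= 2 * h
                e0 = total_energy(c, p, chan)
                grad = -(e1 - e0) / (2 * h)
                assert abs(grad - f[i, d]) < 1e-6


class TestIntegrator:
    def test_ballistic_limit(self):
        """Zero forces, friction and noise: uniform straight-line motion."""
        p = ModelParams(N=2, gamma=0.0)
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        conf = Conformation(pos.copy(), np.array([1, 2]), closed=False)
        conf.velocities = np.array([[1.0, 0.5, -0.25], [0.0, 0.0, 1.0]])
        v0 = conf.velocities.copy()
        from linkedrings.dynamics import langevin_step
        langevin_step(conf, p, ChannelSpec.bulk(), rng_seed=0, n_steps=200)
        assert np.allclose(conf.velocities, v0, atol=1e-12)
        assert np.allclose(conf.positions, pos + v0 * 200 * p.dt, atol=1e-9)

    def test_nve_energy_conservation(self, rng):
        """gamma = 0, no noise: symplectic velocity Verlet conserves energy."""
        p = ModelParams(N=40)
        conf = catalog_conformation("2_1^2", 40)
        conf.velocities = maxwell_velocities(conf.n_beads, p, rng)
        bulk = ChannelSpec.bulk()
        simulate(conf, p, bulk, duration=20.0, sample_interval=20.0, seed=4)
        pn = p.with_(gamma=0.0)

        def etot(c):
            return total_energy(c, pn, bulk) + \
                0.5 * pn.mass * float(np.sum(c.velocities ** 2))

        e0 = etot(conf)
        simulate(conf, pn, bulk, duration=5.0, sample_interval=5.0, seed=5)
        e1 = etot(conf)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_equipartition(self, rng):
        """Kinetic temperature of an equilibrated ring within 2% of target."""
        p = ModelParams(N=40)
        conf = catalog_conformation("2_1^2", 40)
        conf.velocities = maxwell_velocities(conf.n_beads, p, rng)
        bulk = ChannelSpec.bulk()
        simulate(conf, p, bulk, duration=50.0, sample_interval=50.0, seed=11)
        temps = []
        for k in range(60):
            simulate(conf, p, bulk, duration=5.0, sample_interval=5.0,
                     seed=100 + k)
            temps.append(kinetic_temperature(conf, p))
        mean = float(np.mean(temps))
        sem = float(np.std(temps, ddof=1) / math.sqrt(len(temps)))
        assert abs(mean - p.temperature) < max(0.02, 3 * sem)

    def test_determinism(self, rng):
        p = ModelParams(N=20)
        conf1 = catalog_conformation("2_1^2", 20)
        conf1.velocities = maxwell_velocities(conf1.n_beads, p,
                                              np.random.default_rng(3))
        conf2 = conf1.copy()
        bulk = ChannelSpec.bulk()
        t1 = simulate(conf1, p, bulk, 5.0, 1.0, seed=42)
        t2 = simulate(conf2, p, bulk, 5.0, 1.0, seed=42)
        assert np.array_equal(t1.frames, t2.frames)
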
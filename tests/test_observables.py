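"""Metric observables, relaxation-time estimators and survival analysis."""

import numpy as np
import pytest

from linkedrings import Conformation
from linkedrings import observables as O
from linkedrings import synthetic as S
from linkedrings.catalog import single_ring_conformation
from linkedrings.errors import CensoredDataError


class TestRadiusOfGyration:
    def test_rigid_circle(self):
        th = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        ring = np.column_stack([5 * np.cos(th), 5 * np.sin(th), 0 * th])
        assert O.radius_of_gyration(ring) == pytest.approx(5.0, rel=1e-6)

    def test_coincident_beads(self):
        assert O.radius_of_gyration(np.ones((7, 3))) == 0.0

    def test_matches_bruteforce_double_sum(self, rng):
        """Rg^2 equals the brute-force mean squared distance to the joint
        centre of mass, summed over both rings and all beads."""
        pos = rng.standard_normal((10, 3))
        conf = Conformation(pos, np.repeat([1, 2], 5))
        rcm = pos.mean(axis=0)
        expected = np.sqrt(sum(np.dot(p - rcm, p - rcm) for p in pos) / 10)
        assert O.radius_of_gyration(conf) == pytest.approx(expected, rel=1e-12)


class TestLongitudinalSpan:
    def test_circle_diameter(self):
        th = np.linspace(0, 2 * np.pi, 720)
        ring = np.column_stack([3 * np.cos(th), 3 * np.sin(th), 0 * th])
        assert O.longitudinal_span(ring) == pytest.approx(6.0, rel=1e-4)

    def test_translation_and_transverse_invariance(self, rng):
        pos = rng.standard_normal((20, 3))
        s0 = O.longitudinal_span(pos)
        assert O.longitudinal_span(pos + [5.0, -2.0, 7.0]) == pytest.approx(s0)
        flipped = pos.copy()
        flipped[:, 1:] = -flipped[:, 1:]
        assert O.longitudinal_span(flipped) == pytest.approx(s0)

    def test_projection_on_random_axis(self, rng):
        pos = rng.standard_normal((20, 3))
        axis = np.array([0.0, 1.0, 0.0])
        expected = pos[:, 1].max() - pos[:, 1].min()
        assert O.longitudinal_span(pos, axis=axis) == pytest.approx(expected)


class TestRelaxationTime:
    def test_exponential_returns_098_tau(self):
        ser = S.make_exp_decay_series(tau=50.0, dt=0.02, n=20000)
        res = O.relaxation_time(ser)
        assert res.tau_A == pytest.approx(0.98 * 50.0, rel=1e-3)
        assert not res.censored

    def test_step_function(self):
        t = np.arange(200, dtype=float)
        f = np.where(t < 80, 1.0, 0.0)
        ser = O.ObservableSeries(t, f, equilibrium_mean=0.0, initial_mean=1.0)
        res = O.relaxation_time(ser)
        assert res.tau_A == pytest.approx(79.5, abs=1.0)

    def test_degenerate_equilibrium_start_raises(self):
        ser = O.ObservableSeries(np.arange(10.0), np.zeros(10),
                                 equilibrium_mean=0.0, initial_mean=0.0)
        with pytest.raises(CensoredDataError):
            O.relaxation_time(ser)

    def test_censored_when_never_below_threshold(self):
        t = np.arange(100, dtype=float)
        ser = O.ObservableSeries(t, 1.0 - 0.001 * t, 0.0, 1.0)
        res = O.relaxation_time(ser)
        assert res.censored

    def test_affine_rescaling_invariance(self):
        """Standardization makes tau_A invariant under A -> a*A + b."""
        ser = S.make_exp_decay_series(tau=30.0, dt=0.05, n=10000,
                                      equilibrium=2.0, initial=7.0)
        res1 = O.relaxation_time(ser)
        ser2 = O.ObservableSeries(ser.times, 3.0 * ser.ensemble_mean - 1.0,
                                  3.0 * 2.0 - 1.0, 3.0 * 7.0 - 1.0)
        res2 = O.relaxation_time(ser2)
        assert res1.tau_A == pytest.approx(res2.tau_A, rel=1e-9)


class TestTerminalAutocorrelation:
    def test_rigid_rotation_closed_form(self):
        """Rotation at angular velocity w about the ring normal: in-plane
        diameter vectors decorrelate as cos(w t); the integral to the
        threshold crossing equals sin(arccos(0.02))/w."""
        conf = single_ring_conformation(40)
        traj = S.make_rigid_rotation(conf, omega=0.05, dt=1.0, n_frames=200)
        res = O.terminal_autocorrelation(traj.frames, traj.times)
        expected = np.sqrt(1 - O.RELAX_CUTOFF ** 2) / 0.05
        assert res.tau_tacf == pytest.approx(expected, rel=0.01)

    def test_frozen_conformation_censored(self):
        conf = single_ring_conformation(20)
        frames = np.repeat(conf.positions[None], 50, axis=0)
        res = O.terminal_autocorrelation(frames)
        assert res.censored
        assert res.correlation[0] == pytest.approx(1.0)

    def test_diffusive_reorientation_recovery(self):
        """Isotropic diffusive reorientation with a known rotational time:
        the integral estimator recovers it within 10%.

        The per-step orientational decorrelation factor rho of the
        random-rotation process is measured independently by Monte Carlo;
        the expected correlation is rho**t, whose cutoff integral is
        0.98 * (-1/ln rho).
        """
        rng = np.random.default_rng(8)
        n_frames, nb = 20000, 8
        sigma_w = np.sqrt(2 * 0.01)

        def rotate(pos, w):
            th = np.linalg.norm(w)
            a = w / th
            c, s = np.cos(th), np.sin(th)
            return (c * pos + s * np.cross(a, pos)
                    + (1 - c) * np.outer(pos @ a, a))

        # independent oracle: exact one-step decorrelation of a unit vector
        oracle_rng = np.random.default_rng(123)
        u = np.array([[1.0, 0.0, 0.0]])
        dots = [rotate(u, oracle_rng.standard_normal(3) * sigma_w)[0] @ u[0]
                for _ in range(200000)]
        rho = float(np.mean(dots))
        tau_r = -1.0 / np.log(rho)

        conf = single_ring_conformation(nb)
        taus = []
        for rep in range(3):
            frames = np.empty((n_frames, nb, 3))
            pos = conf.positions - conf.positions.mean(axis=0)
            for k in range(n_frames):
                frames[k] = pos
                pos = rotate(pos, rng.standard_normal(3) * sigma_w)
            res = O.terminal_autocorrelation(
                frames, np.arange(n_frames, dtype=float))
            taus.append(res.tau_tacf)
        assert np.mean(taus) == pytest.approx(0.98 * tau_r, rel=0.10)


class TestEquilibriumAverage:
    def _make_trajs(self, values, last_k=5):
        from linkedrings.dynamics import Trajectory
        trajs = []
        for v in values:
            frames = np.asarray(v)[:, None, None] * np.ones((1, 4, 3))
            trajs.append(Trajectory(np.arange(len(v), dtype=float), frames,
                                    np.ones(4, dtype=np.int64)))
        return trajs

    def test_constant_zero_error(self):
        trajs = self._make_trajs([[3.0] * 8] * 6)
        mean, sem = O.equilibrium_average(trajs, lambda c: c.positions[0, 0])
        assert mean == 3.0 and sem == 0.0

    def test_uses_last_k_times_m_conformations(self):
        # last-5 convention: 5 samples x M trajectories enter the average
        vals = [[0, 0, 0, 1, 1, 1, 1, 1], [0, 0, 0, 2, 2, 2, 2, 2]]
        trajs = self._make_trajs(vals)
        mean, _ = O.equilibrium_average(trajs, lambda c: c.positions[0, 0])
        assert mean == pytest.approx(1.5)

    def test_block_sem_matches_resampling(self, rng):
        """SEM from trajectory blocks agrees with the spread of the
        per-trajectory means (trajectories independent by construction)."""
        m, k = 200, 5
        data = rng.normal(size=(m, k + 3))
        trajs = self._make_trajs(data.tolist())
        mean, sem = O.equilibrium_average(trajs, lambda c: c.positions[0, 0])
        blocks = data[:, -k:].mean(axis=1)
        assert mean == pytest.approx(blocks.mean())
        assert sem == pytest.approx(blocks.std(ddof=1) / np.sqrt(m), rel=1e-9)

    def test_too_few_samples_raises(self):
        trajs = self._make_trajs([[1.0, 2.0]])
        with pytest.raises(CensoredDataError):
            O.equilibrium_average(trajs, lambda c: 0.0)


class TestSurvivalAnalysis:
    def test_unit_step(self):
        grid = np.arange(0.0, 100.0, 10.0)
        flags = grid[None, :] >= 50.0
        flags = np.repeat(flags, 20, axis=0)
        res = O.survival_analysis(flags, grid)
        assert res.survival[0] == 1.0
        assert np.all(np.diff(res.survival) <= 1e-12)

    def test_exponential_recovery(self):
        lam = 1e-3
        times = S.make_exp_disengagement(lam, 500, seed=4)
        grid = np.arange(0.0, 2e4, 100.0)
        flags = times[:, None] <= grid[None, :]
        res = O.survival_analysis(flags, grid)
        assert not res.censored
        assert res.tau_surv == pytest.approx(1.0 / lam, rel=0.10)

    def test_integral_definition_option(self):
        lam = 1e-3
        times = S.make_exp_disengagement(lam, 500, seed=4)
        grid = np.arange(0.0, 5e4, 100.0)
        flags = times[:, None] <= grid[None, :]
        res = O.survival_analysis(flags, grid, definition="integral")
        assert res.definition == "integral"
        assert res.tau_surv == pytest.approx(1.0 / lam, rel=0.10)

    def test_censoring_gives_lower_bound(self):
        grid = np.arange(0.0, 1000.0, 50.0)
        flags = np.zeros((30, grid.size), dtype=bool)  # nobody disengages
        res = O.survival_analysis(flags, grid)
        assert res.censored and res.n_censored == 30
        assert res.tau_surv == pytest.approx(grid[-1], rel=0.1)

    def test_monotone_nonincreasing(self, rng):
        grid = np.arange(0.0, 300.0, 10.0)
        t_dis = rng.exponential(100.0, size=50)
        flags = t_dis[:, None] <= grid[None, :]
        res = O.survival_analysis(flags, grid)
        assert np.all(np.diff(res.survival) <= 1e-12)
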
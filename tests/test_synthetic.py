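"""Synthetic fixture generators: determinism and ground-truth recovery."""

import numpy as np
import pytest

from linkedrings import observables as O
from linkedrings import synthetic as S
from linkedrings import topology as T


class TestParametricLinks:
    def test_hopf_linking_number(self):
        conf = S.make_parametric_link("2_1^2", 100)
        assert abs(T.gauss_linking_number(*conf.rings())) == 1

    def test_solomon_linking_number(self):
        conf = S.make_parametric_link("4_1^2", 100)
        assert abs(T.gauss_linking_number(*conf.rings())) == 2

    def test_split_pair_separable(self):
        conf = S.make_parametric_link("0_1^2", 60)
        r1, r2 = conf.rings()
        assert T.gauss_linking_number(r1, r2) == 0
        assert T.is_linearly_separable(r1, r2)

    def test_scale_leaves_topology_unchanged(self):
        small = S.make_parametric_link("6_1^2", 60, scale=0.5)
        big = S.make_parametric_link("6_1^2", 60, scale=3.0)
        assert T.identify_link_type(small) == T.identify_link_type(big) == "6_1^2"


class TestOuSeries:
    def test_relaxation_time_recovery(self):
        """Ensemble-mean decay of replicas started at x0 recovers tau."""
        tau, dt = 40.0, 0.5
        x = S.make_ou_series(tau, dt, 2000, seed=9, n_replicas=300,
                             x0=1.0, noise=0.1)
        ser = O.ObservableSeries(np.arange(2000) * dt, x.mean(axis=0),
                                 equilibrium_mean=0.0, initial_mean=1.0)
        res = O.relaxation_time(ser)
        assert res.tau_A == pytest.approx(0.98 * tau, rel=0.10)

    def test_autocorrelation_time_recovery(self):
        """Stationary-series autocorrelation time equals tau within 10%."""
        tau, dt, n = 20.0, 1.0, 100000
        x = S.make_ou_series(tau, dt, n, seed=10, n_replicas=4, x0=0.0)
        acfs = []
        lags = np.arange(400)
        for row in x:
            r = row - row.mean()
            acf = np.correlate(r, r, mode="full")[n - 1:n - 1 + 400]
            acfs.append(acf / acf[0])
        acf = np.mean(acfs, axis=0)
        fit = np.polyfit(lags[:40] * dt, np.log(acf[:40]), 1)
        assert -1.0 / fit[0] == pytest.approx(tau, rel=0.10)

    def test_white_noise_limit(self):
        x = S.make_ou_series(1e-9, 1.0, 5000, seed=3, n_replicas=100, x0=1.0)
        # the ensemble mean collapses to ~0 after the very first step
        assert abs(x[:, 1:].mean()) < 0.01

    def test_seed_determinism(self):
        a = S.make_ou_series(10.0, 0.1, 100, seed=5, n_replicas=3)
        b = S.make_ou_series(10.0, 0.1, 100, seed=5, n_replicas=3)
        assert np.array_equal(a, b)


class TestExpDisengagement:
    def test_rate_recovery(self):
        times = S.make_exp_disengagement(1e-3, 5000, seed=2)
        assert times.mean() == pytest.approx(1000.0, rel=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            S.make_exp_disengagement(0.0, 10, seed=1)
        with pytest.raises(ValueError):
            S.make_exp_disengagement(1.0, 0, seed=1)


class TestRigidRotation:
    def test_rotation_preserves_shape(self):
        conf = S.make_parametric_link("2_1^2", 30)
        traj = S.make_rigid_rotation(conf, omega=0.1, dt=1.0, n_frames=10)
        d0 = np.linalg.norm(traj.frames[0][0] - traj.frames[0][7])
        d9 = np.linalg.norm(traj.frames[9][0] - traj.frames[9][7])
        assert d0 == pytest.approx(d9, rel=1e-9)
        assert traj.n_frames == 10
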
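"""Property-based invariants (hypothesis, derandomized)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from linkedrings import Conformation
from linkedrings import observables as O
from linkedrings import synthetic as S
from linkedrings import topology as T

SETTINGS = dict(derandomize=True, max_examples=25, deadline=None)

finite = st.floats(-50.0, 50.0, allow_nan=False)
points = hnp.arrays(np.float64, st.tuples(st.integers(5, 24),
                                          st.just(3)), elements=finite)


class TestMetricInvariances:
    @settings(**SETTINGS)
    @given(points, st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20))
    def test_gyration_radius_translation_invariant(self, pos, dx, dy, dz):
        conf = Conformation(pos, np.ones(len(pos), dtype=np.int64),
                            closed=False)
        r0 = O.radius_of_gyration(conf)
        conf.positions = pos + np.array([dx, dy, dz])
        assert O.radius_of_gyration(conf) == pytest.approx(r0, abs=1e-8)

    @settings(**SETTINGS)
    @given(points, st.floats(0.1, 10.0))
    def test_gyration_radius_scales_linearly(self, pos, scale):
        r0 = O.radius_of_gyration(pos)
        assert O.radius_of_gyration(pos * scale) == pytest.approx(
            scale * r0, rel=1e-9, abs=1e-9)

    @settings(**SETTINGS)
    @given(points)
    def test_span_bounded_by_total_extent(self, pos):
        s = O.longitudinal_span(pos)
        assert 0 <= s <= np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)) + 1e-12


class TestRelaxationEstimatorProperties:
    @settings(**SETTINGS)
    @given(st.floats(1.0, 500.0), st.floats(-5, 5),
           st.floats(0.1, 10.0), st.floats(-10, 10))
    def test_affine_rescaling_invariance(self, tau, eq, a, b):
        """tau_A is invariant under A -> a*A + b (standardization)."""
        ser = S.make_exp_decay_series(tau=tau, dt=tau / 200, n=2000,
                                      equilibrium=eq, initial=eq + 3.0)
        t1 = O.relaxation_time(ser).tau_A
        ser2 = O.ObservableSeries(ser.times, a * ser.ensemble_mean + b,
                                  a * eq + b, a * (eq + 3.0) + b)
        t2 = O.relaxation_time(ser2).tau_A
        assert t1 == pytest.approx(t2, rel=1e-9)

    @settings(**SETTINGS)
    @given(st.floats(1.0, 100.0))
    def test_exponential_integral_value(self, tau):
        ser = S.make_exp_decay_series(tau=tau, dt=tau / 400, n=4000)
        assert O.relaxation_time(ser).tau_A == pytest.approx(0.98 * tau,
                                                             rel=2e-3)


class TestSurvivalProperties:
    @settings(**SETTINGS)
    @given(st.integers(0, 10_000))
    def test_survival_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.arange(0.0, 200.0, 10.0)
        t_dis = rng.exponential(rng.uniform(10, 300), size=25)
        flags = t_dis[:, None] <= grid[None, :]
        res = O.survival_analysis(flags, grid)
        assert res.survival[0] == 1.0 or flags[:, 0].any()
        assert np.all(np.diff(res.survival) <= 1e-12)


class TestTopologyProperties:
    @settings(**SETTINGS)
    @given(st.integers(0, 10_000))
    def test_linking_number_rigid_motion_invariant(self, seed):
        rng = np.random.default_rng(seed)
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        c1 = np.column_stack([np.cos(th), np.sin(th), 0 * th])
        c2 = np.column_stack([1 + np.cos(th), 0 * th, np.sin(th)])
        lk = T.gauss_linking_number(c1, c2)
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, [0, 1]] = q[:, [1, 0]]
        shift = rng.uniform(-10, 10, 3)
        scale = rng.uniform(0.2, 5.0)
        assert T.gauss_linking_number(scale * c1 @ q + shift,
                                      scale * c2 @ q + shift) == lk
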
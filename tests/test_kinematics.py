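"""Kinematics: smoothing, circle fit, angular velocity, mask, inversions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rotaspike as rs
from conftest import constant_omega_kin
from rotaspike.kinematics import (
    fit_circle,
    smooth_coordinates,
    wrap_to_pi,
    compute_head_angle,
    compute_angular_velocity,
    movement_mask,
    DegenerateTrajectoryError,
)

FR = 25.0
DT = 1.0 / FR


def make_trace(x, y, dt=DT):
    t = np.arange(len(x)) * dt
    return rs.TrackingTrace(t, np.asarray(x, float), np.asarray(y, float))


class TestSmoothing:
    def test_constant_trace_is_fixed_point(self):
        tr = make_trace(np.full(100, 3.0), np.full(100, -2.0))
        sm = smooth_coordinates(tr)
        assert np.allclose(sm.x, 3.0) and np.allclose(sm.y, -2.0)
        assert np.array_equal(sm.t, tr.t)

    def test_boxcar_of_line_is_line_in_interior(self):
        t = np.arange(200) * DT
        tr = rs.TrackingTrace(t, 2.0 * t + 1.0, -0.5 * t)
        sm = smooth_coordinates(tr, window_s=0.6)
        interior = slice(16, -16)  # full +-0.3 s window available
        assert np.allclose(sm.x[interior], tr.x[interior], atol=1e-10)
        assert np.allclose(sm.y[interior], tr.y[interior], atol=1e-10)

    def test_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(size=150), rng.normal(size=150))
        sm = smooth_coordinates(tr, window_s=0.6)
        for i in range(len(tr)):
            inside = np.abs(tr.t - tr.t[i]) <= 0.3 + 1e-9
            assert sm.x[i] == pytest.approx(tr.x[inside].mean(), abs=1e-12)
            assert sm.y[i] == pytest.approx(tr.y[inside].mean(), abs=1e-12)

    def test_rejects_nonpositive_window(self):
        tr = make_trace(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            smooth_coordinates(tr, window_s=0.0)


class TestHeadAngle:
    def test_unit_circle_angles_recovered(self):
        ang = np.linspace(0.1, 2 * np.pi - 0.1, 60)
        tr = make_trace(np.cos(ang), np.sin(ang))
        kin = compute_head_angle(tr)
        assert np.allclose(kin.theta, ang, atol=1e-9)

    def test_full_ccw_revolution_unwraps_to_two_pi(self):
        ang = np.linspace(0.0, 2 * np.pi, 101)
        tr = make_trace(np.cos(ang), np.sin(ang))
        kin = compute_head_angle(tr)
        assert kin.theta_unwrapped[-1] - kin.theta_unwrapped[0] == pytest.approx(
            2 * np.pi, abs=1e-9
        )

    def test_noisy_circle_center_recovered(self):
        # grid-search oracle: best centre over a coarse lattice
        rng = np.random.default_rng(3)
        radius, cx, cy = 10.0, 2.0, -1.0
        ang = rng.uniform(0, 2 * np.pi, 600)
        x = cx + radius * np.cos(ang) + rng.normal(0, 0.05 * radius, 600)
        y = cy + radius * np.sin(ang) + rng.normal(0, 0.05 * radius, 600)
        fx, fy, fr = fit_circle(x, y)
        assert np.hypot(fx - cx, fy - cy) < 0.02 * radius
        grid = np.linspace(-0.5, 0.5, 21)
        best = min(
            ((gx, gy) for gx in cx + grid for gy in cy + grid),
            key=lambda c: np.std(np.hypot(x - c[0], y - c[1])),
        )
        assert np.hypot(fx - best[0], fy - best[1]) < 0.02 * radius

    def test_degenerate_trajectory_raises(self):
        t = np.arange(20) * DT
        with pytest.raises(DegenerateTrajectoryError):
            compute_head_angle(rs.TrackingTrace(t, t, 2 * t + 1))  # collinear

    def test_too_few_frames_raises(self):
        tr = make_trace(np.cos([0.1, 0.2, 0.3]), np.sin([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            compute_head_angle(tr)


class TestAngularVelocity:
    def _kin_from_unwrapped(self, unwrapped, radius=1.0):
        tr = make_trace(radius * np.cos(unwrapped), radius * np.sin(unwrapped))
        kin = compute_head_angle(tr)
        return compute_angular_velocity(kin)

    def test_constant_rotation_constant_omega_zero_alpha(self):
        kin = self._kin_from_unwrapped(1.1 * np.arange(100) * DT)
        assert np.allclose(kin.omega, 1.1, atol=1e-8)
        assert np.allclose(kin.alpha, 0.0, atol=1e-6)

    def test_no_wraparound_spike_at_two_pi_crossing(self):
        kin = self._kin_from_unwrapped(np.linspace(5.8, 7.0, 100))  # crosses 2*pi
        assert np.max(np.abs(kin.omega)) < 2 * np.abs(
            (7.0 - 5.8) / (99 * DT)
        )

    def test_matches_finite_difference_oracle_exactly(self):
        rng = np.random.default_rng(1)
        unwrapped = np.cumsum(rng.uniform(-0.05, 0.08, 200))
        kin = self._kin_from_unwrapped(unwrapped)
        d = np.diff(kin.theta_unwrapped) / np.diff(kin.t)
        oracle = np.append(d, d[-1])
        assert np.array_equal(kin.omega, oracle)

    def test_too_few_frames_raises(self):
        kin = compute_head_angle(
            make_trace(np.cos(np.linspace(0, 1, 10)), np.sin(np.linspace(0, 1, 10)))
        )
        kin.t = kin.t[:2]
        kin.theta_unwrapped = kin.theta_unwrapped[:2]
        with pytest.raises(ValueError):
            compute_angular_velocity(kin)


class TestMovementMask:
    def test_stationary_platform_never_moving(self):
        # a fixed point is degenerate for the circle fit; build the mask directly
        constant = np.full(50, 0.3)
        tr = make_trace(10 * np.cos(constant), 10 * np.sin(constant))
        kin = rs.KinematicsSeries(
            t=tr.t, theta=constant, theta_unwrapped=constant, x=tr.x, y=tr.y,
            center=(0, 0), radius_cm=10.0,
            omega=np.zeros(50), alpha=np.zeros(50),
        )
        kin = movement_mask(kin, cutoff_cm_s=1.0)
        assert not kin.moving.any()

    def test_fast_constant_rotation_always_moving(self):
        k = constant_omega_kin(omega=0.5, radius=10.0)  # 5 cm/s linear speed
        assert k.moving.all()

    def test_mask_partitions_session(self, kin):
        assert kin.movement_time_s + kin.rest_time_s == pytest.approx(
            kin.duration_s, abs=1e-6
        )
        assert np.all(kin.moving == (kin.lin_speed > 1.0))


class TestInversions:
    def _kin_with_theta(self, theta):
        n = len(theta)
        return rs.KinematicsSeries(
            t=np.arange(n) * DT, theta=np.mod(theta, 2 * np.pi),
            theta_unwrapped=np.asarray(theta, float),
            x=np.cos(theta), y=np.sin(theta), center=(0, 0), radius_cm=1.0,
        )

    def test_monotone_rotation_has_none(self):
        assert rs.count_inversions(self._kin_with_theta(0.05 * np.arange(400))) == 0

    def test_single_reversal_counted_once(self):
        up = 0.05 * np.arange(200)
        theta = np.concatenate([up, up[-1] - 0.05 * np.arange(1, 200)])
        assert rs.count_inversions(self._kin_with_theta(theta)) == 1

    @pytest.mark.parametrize("k", [0, 1, 4, 9])
    def test_scheduled_reversals_recovered(self, k):
        spec = rs.SessionSpec(duration_s=240.0, n_inversions=k, seed=11)
        kin = rs.compute_kinematics(rs.generate_rotation_trajectory(spec))
        assert rs.count_inversions(kin) == k

    @given(offset=st.floats(0.0, 2 * np.pi))
    def test_invariant_to_constant_rotation_offset(self, offset):
        rng = np.random.default_rng(5)
        theta = np.cumsum(rng.uniform(-0.2, 0.25, 300))
        a = rs.count_inversions(self._kin_with_theta(theta))
        b = rs.count_inversions(self._kin_with_theta(theta + offset))
        assert a == b


class TestSummary:
    def test_constant_rotation_summary(self):
        k = constant_omega_kin(omega=1.1, radius=10.0)
        s = rs.summarize_kinematics(k)
        # truncated boxcar windows compress the angle at the session edges,
        # biasing the mean by ~0.5% on a 60 s session
        assert s.mean_angular_speed_rad_s == pytest.approx(1.1, rel=1e-2)
        assert s.rest_time_s == 0.0
        assert s.n_inversions == 0

    def test_all_rest_session(self):
        n = 100
        kin = rs.KinematicsSeries(
            t=np.arange(n) * DT, theta=np.full(n, 0.3),
            theta_unwrapped=np.full(n, 0.3), x=np.full(n, 1.0),
            y=np.zeros(n), center=(0, 0), radius_cm=1.0,
            omega=np.zeros(n), alpha=np.zeros(n),
        )
        kin = movement_mask(kin, cutoff_cm_s=1.0)
        s = rs.summarize_kinematics(kin)
        assert s.mean_angular_speed_rad_s is None
        assert s.reason == "no_movement_frames"
        assert s.rest_time_s == pytest.approx(kin.duration_s)

    def test_generator_round_trip_matches_spec(self, base_session):
        spec, _, kin = base_session
        s = rs.summarize_kinematics(kin)
        assert s.n_inversions == spec.n_inversions
        assert s.mean_angular_speed_rad_s == pytest.approx(
            spec.target_angular_speed_rad_s, rel=0.15
        )
        assert s.rest_time_s == pytest.approx(
            spec.rest_fraction * spec.duration_s, rel=0.2
        )


class TestWrap:
    @given(st.floats(-50.0, 50.0))
    def test_wrap_lands_in_half_open_interval(self, d):
        w = wrap_to_pi(d)
        assert -np.pi < w <= np.pi
        # same angle modulo 2*pi
        assert np.isclose(np.mod(w - d, 2 * np.pi) % (2 * np.pi), 0, atol=1e-9) or \
            np.isclose(np.mod(w - d, 2 * np.pi), 2 * np.pi, atol=1e-9)

    def test_rewrap_matches_theta(self, kin):
        assert np.allclose(
            np.mod(kin.theta_unwrapped, 2 * np.pi), kin.theta, atol=1e-9
        )
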
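import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rotaspike as rs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_session():
    """One 120 s rotation session analysed once and shared across tests."""
    spec = rs.SessionSpec(duration_s=120.0, n_inversions=3, rest_fraction=0.2, seed=1)
    trace = rs.generate_rotation_trajectory(spec)
    kin = rs.compute_kinematics(trace)
    return spec, trace, kin


@pytest.fixture(scope="session")
def kin(base_session):
    return base_session[2]


@pytest.fixture(scope="session")
def hd_cell_spikes(kin):
    """A sharply tuned HD cell on the shared session."""
    cell = rs.CellSpec(base_rate_hz=4.0, kappa=4.0, preferred_dir_rad=1.0, seed=7)
    return rs.generate_spike_train(kin, cell)


def manual_constant_kin(
    omega=1.1, duration=60.0, frame_rate=25.0, radius=10.0, theta0=0.0
):
    """Exact constant-rotation kinematics built field by field (no smoothing),
    for tests needing bit-exact occupancy and bin assignment."""
    dt = 1.0 / frame_rate
    t = np.arange(int(round(duration * frame_rate))) * dt
    unwrapped = theta0 + omega * t
    n = t.size
    return rs.KinematicsSeries(
        t=t,
        theta=np.mod(unwrapped, 2 * np.pi),
        theta_unwrapped=unwrapped,
        x=radius * np.cos(unwrapped),
        y=radius * np.sin(unwrapped),
        center=(0.0, 0.0),
        radius_cm=radius,
        omega=np.full(n, omega),
        alpha=np.zeros(n),
        lin_speed=np.full(n, abs(omega) * radius),
        moving=np.full(n, abs(omega) * radius > 1.0),
    )


def constant_omega_kin(omega=1.1, duration=60.0, frame_rate=25.0, radius=10.0):
    """Noise-free constant-rotation kinematics built directly (no generator)."""
    dt = 1.0 / frame_rate
    t = np.arange(int(duration * frame_rate)) * dt
    theta = np.mod(omega * t, 2 * np.pi)
    x = radius * np.cos(omega * t)
    y = radius * np.sin(omega * t)
    trace = rs.TrackingTrace(t, x, y)
    return rs.compute_kinematics(trace)
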
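"""Kinematics of passive rotation from LED tracking.

The only positional input to the pipeline is a single LED tracked at the video
frame rate (25 Hz, i.e. 40 ms frames).  Because the animal is head-fixed on a
rotating platform, the LED moves on a circle around the rotation centre and
the head-direction angle is the LED polar angle around that centre (plus a
fixed, configurable offset).  This module turns the raw trace into:

* smoothed coordinates (600 ms centred boxcar),
* head angle ``theta`` in [0, 2*pi) and its unwrapped counterpart,
* angular velocity ``omega`` and acceleration ``alpha`` by frame-to-frame
  finite differences (``alpha = d omega / dt`` with dt the frame interval),
* linear LED speed and the movement mask (speed > 1 cm/s), which gates every
  downstream spike analysis,
* the direction-inversion count and a per-session kinematic summary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

__all__ = [
    "TrackingTrace",
    "KinematicsSeries",
    "SessionKinematicsSummary",
    "wrap_to_pi",
    "smooth_coordinates",
    "fit_circle",
    "compute_head_angle",
    "compute_angular_velocity",
    "movement_mask",
    "count_inversions",
    "summarize_kinematics",
    "compute_kinematics",
    "DegenerateTrajectoryError",
]


class DegenerateTrajectoryError(ValueError):
    """Raised when the LED trajectory does not define a rotation circle."""


def wrap_to_pi(d: np.ndarray) -> np.ndarray:
    """Map angle differences into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(d, dtype=float), TWO_PI)


@dataclass(frozen=True)
class TrackingTrace:
    """Raw (or smoothed) LED positions per video frame."""

    t: np.ndarray  #: seconds, strictly increasing, ~40 ms spacing
    x: np.ndarray  #: cm
    y: np.ndarray  #: cm

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty tracking trace")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if len(self) > 1 else np.nan

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackingTrace":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy())


@dataclass
class KinematicsSeries:
    """All kinematic series on the video frame grid."""

    t: np.ndarray
    theta: np.ndarray               #: head angle, [0, 2*pi)
    theta_unwrapped: np.ndarray     #: continuous angle
    x: np.ndarray                   #: smoothed LED x (cm)
    y: np.ndarray                   #: smoothed LED y (cm)
    center: tuple[float, float]
    radius_cm: float
    omega: Optional[np.ndarray] = None      #: rad/s (signed)
    alpha: Optional[np.ndarray] = None      #: rad/s^2
    lin_speed: Optional[np.ndarray] = None  #: cm/s
    moving: Optional[np.ndarray] = None     #: bool mask, lin_speed > cutoff

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        """Total covered time: one frame interval per frame."""
        return float(self.t[-1] - self.t[0] + self.dt)

    @property
    def movement_time_s(self) -> float:
        return float(np.sum(self.moving) * self.dt)

    @property
    def rest_time_s(self) -> float:
        return float(np.sum(~self.moving) * self.dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "theta_rad": self.theta,
                "theta_unwrapped_rad": self.theta_unwrapped,
                "omega_rad_s": self.omega,
                "alpha_rad_s2": self.alpha,
                "lin_speed_cm_s": self.lin_speed,
                "moving": self.moving,
            }
        )


@dataclass(frozen=True)
class SessionKinematicsSummary:
    """Per-session kinematic covariates.

    ``mean_accel`` averages alpha over alpha > 0 movement frames,
    ``mean_decel`` over alpha < 0 movement frames; either is ``None`` when no
    such frames exist, with the reason recorded.
    """

    mean_angular_speed_rad_s: Optional[float]
    mean_accel_rad_s2: Optional[float]
    mean_decel_rad_s2: Optional[float]
    n_inversions: int
    movement_time_s: float
    rest_time_s: float
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "mean_angular_speed_rad_s": self.mean_angular_speed_rad_s,
            "mean_accel_rad_s2": self.mean_accel_rad_s2,
            "mean_decel_rad_s2": self.mean_decel_rad_s2,
            "n_inversions": self.n_inversions,
            "movement_time_s": self.movement_time_s,
            "rest_time_s": self.rest_time_s,
            "reason": self.reason,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def smooth_coordinates(trace: TrackingTrace, window_s: float = 0.6) -> TrackingTrace:
    """Centred rectangular (boxcar) moving average of the LED coordinates.

    Each output sample is the mean of all frames within +-window_s/2 of its
    timestamp; at the edges the window is truncated to the available frames.
    Timestamps are unchanged.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = trace.t
    half = window_s / 2.0 + 1e-9  # tolerate float jitter on the frame grid
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    n = (hi - lo).astype(float)
    csx = np.concatenate(([0.0], np.cumsum(trace.x)))
    csy = np.concatenate(([0.0], np.cumsum(trace.y)))
    return TrackingTrace(t, (csx[hi] - csx[lo]) / n, (csy[hi] - csy[lo]) / n)


def fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit (Kasa method).

    Solves ``a*x + b*y + c = x^2 + y^2`` for (a, b, c); the centre is
    (a/2, b/2) and the radius sqrt(c + cx^2 + cy^2).  Deterministic and
    closed-form; adequate for a full-circle trajectory.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateTrajectoryError("collinear or degenerate LED trajectory")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 1e-12:
        raise DegenerateTrajectoryError("zero-radius LED trajectory")
    return float(cx), float(cy), float(np.sqrt(r2))


def compute_head_angle(
    trace: TrackingTrace, offset_rad: float = 0.0
) -> KinematicsSeries:
    """Head angle from the (smoothed) LED trace.

    The rotation centre is estimated by a least-squares circle fit; the head
    angle is the LED polar angle around it plus ``offset_rad`` (the LED sits
    on the sagittal plane, so the offset is a fixed rotation of the tuning
    curve and defaults to 0).
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 frames to estimate the rotation centre")
    cx, cy, radius = fit_circle(trace.x, trace.y)
    theta = np.mod(np.arctan2(trace.y - cy, trace.x - cx) + offset_rad, TWO_PI)
    theta_unwrapped = np.unwrap(theta)
    return KinematicsSeries(
        t=trace.t,
        theta=theta,
        theta_unwrapped=theta_unwrapped,
        x=trace.x,
        y=trace.y,
        center=(cx, cy),
        radius_cm=radius,
    )


def compute_angular_velocity(kin: KinematicsSeries) -> KinematicsSeries:
    """Fill omega and alpha by forward finite differences.

    ``omega[i] = (theta_unwrapped[i+1] - theta_unwrapped[i]) / dt`` with the
    last value repeated so every series shares the frame grid; ``alpha`` is
    the same difference of omega.  Differences use the unwrapped angle, so
    2*pi crossings produce no spikes.
    """
    if kin.t.size < 3:
        raise ValueError("need at least 3 frames for angular velocity")
    dt = np.diff(kin.t)
    omega = np.diff(kin.theta_unwrapped) / dt
    omega = np.append(omega, omega[-1])
    alpha = np.diff(omega[:-1]) / dt[:-1]
    alpha = np.concatenate([alpha, [alpha[-1], alpha[-1]]])
    kin.omega = omega
    kin.alpha = alpha
    return kin


def movement_mask(
    kin: KinematicsSeries, cutoff_cm_s: float = 1.0
) -> KinematicsSeries:
    """Fill linear LED speed and the rest/rotation partition.

    Linear speed is the frame-to-frame displacement of the smoothed LED
    coordinates divided by the frame interval (last value repeated);
    ``moving = lin_speed > cutoff``.  The mask gates all downstream spike
    selection: only movement-period spikes enter the HD, theta and speed
    analyses.
    """
    dt = np.diff(kin.t)
    disp = np.hypot(np.diff(kin.x), np.diff(kin.y))
    speed = disp / dt
    speed = np.append(speed, speed[-1])
    kin.lin_speed = speed
    kin.moving = speed > cutoff_cm_s
    return kin


def count_inversions(kin: KinematicsSeries, eps_rad: float = 1e-4) -> int:
    """Count direction reversals of the platform rotation.

    A reversal is a sign change between two consecutive frame-to-frame angle
    differences.  Raw differences whose magnitude exceeds pi are wraparound
    artifacts of the [0, 2*pi) representation and are first re-mapped into
    (-pi, pi]; differences smaller than ``eps_rad`` in magnitude (rest
    chatter) do not toggle the sign state.
    """
    d = wrap_to_pi(np.diff(kin.theta))
    d = d[np.abs(d) > eps_rad]
    if d.size < 2:
        return 0
    s = np.sign(d)
    return int(np.sum(s[1:] != s[:-1]))


def summarize_kinematics(
    kin: KinematicsSeries, eps_rad: float = 1e-4
) -> SessionKinematicsSummary:
    """Session-level kinematic summary over movement frames."""
    if kin.omega is None or kin.moving is None:
        raise ValueError("kinematics incomplete: run the full pipeline first")
    mov = kin.moving
    n_inv = count_inversions(kin, eps_rad=eps_rad)
    if not mov.any():
        return SessionKinematicsSummary(
            None, None, None, n_inv, 0.0, kin.rest_time_s, reason="no_movement_frames"
        )
    speed = float(np.mean(np.abs(kin.omega[mov])))
    acc = kin.alpha[mov & (kin.alpha > 0)]
    dec = kin.alpha[mov & (kin.alpha < 0)]
    return SessionKinematicsSummary(
        mean_angular_speed_rad_s=speed,
        mean_accel_rad_s2=float(np.mean(acc)) if acc.size else None,
        mean_decel_rad_s2=float(np.mean(dec)) if dec.size else None,
        n_inversions=n_inv,
        movement_time_s=kin.movement_time_s,
        rest_time_s=kin.rest_time_s,
    )


def compute_kinematics(
    trace: TrackingTrace,
    window_s: float = 0.6,
    cutoff_cm_s: float = 1.0,
    offset_rad: float = 0.0,
) -> KinematicsSeries:
    """Full chain: smooth -> head angle -> angular velocity -> movement mask."""
    smoothed = smooth_coordinates(trace, window_s=window_s)
    kin = compute_head_angle(smoothed, offset_rad=offset_rad)
    kin = compute_angular_velocity(kin)
    kin = movement_mask(kin, cutoff_cm_s=cutoff_cm_s)
    return kin
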
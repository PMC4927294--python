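"""Angular-velocity (speed) modulation of firing.

The speed score is the Pearson product-moment correlation between the
instantaneous firing rate (spike count per 40 ms video frame divided by the
frame duration, unsmoothed) and the instantaneous angular speed over movement
frames.  Because platform rotation is bidirectional, speed is unsigned |omega|
by default; the signed-omega correlation is reported as a secondary value.
Significance uses the same rigid whole-train circular time-shift null as the
head-direction test, at the 95th percentile.  Rest-versus-rotation firing
rates are spike counts divided by time within each side of the movement mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinematics import KinematicsSeries
from .spikes import frame_indices

__all__ = [
    "SpeedResult",
    "instantaneous_rate",
    "speed_score",
    "shuffle_test_speed",
    "rest_vs_rotation_rates",
    "analyze_speed",
]


@dataclass
class SpeedResult:
    speed_score: Optional[float]
    speed_score_signed: Optional[float]
    p_value: Optional[float]
    is_speed_modulated: Optional[bool]
    rate_rest_hz: Optional[float]
    rate_rotation_hz: Optional[float]
    reason: Optional[str] = None
    rest_reason: Optional[str] = None
    null_distribution: Optional[np.ndarray] = field(default=None, repr=False)


def instantaneous_rate(
    spike_times: np.ndarray, kin: KinematicsSeries
) -> np.ndarray:
    """Firing rate per video frame (count / frame duration), unsmoothed."""
    idx = frame_indices(spike_times, kin)
    counts = np.bincount(idx[idx >= 0], minlength=kin.t.size).astype(float)
    return counts / kin.dt


def _pearson(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def speed_score(
    rate: np.ndarray, kin: KinematicsSeries
) -> tuple[Optional[float], Optional[float], Optional[str]]:
    """Pearson r between instantaneous rate and angular speed.

    Returns ``(score_abs, score_signed, reason)`` computed over movement
    frames; the scores are ``None`` with a reason code when either series has
    zero variance there.
    """
    if kin.moving is None or kin.omega is None:
        raise ValueError("kinematics incomplete")
    mov = kin.moving
    if mov.sum() < 2:
        return None, None, "too_few_movement_frames"
    r = rate[mov]
    score = _pearson(r, np.abs(kin.omega[mov]))
    signed = _pearson(r, kin.omega[mov])
    if score is None:
        return None, None, "zero_variance"
    return score, signed, None


def shuffle_test_speed(
    spike_times: np.ndarray,
    kin: KinematicsSeries,
    n_perm: int = 1000,
    min_shift_s: float = 20.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, np.ndarray, float]:
    """Rigid-shift permutation test of the speed score.

    Same null scheme as the HD test: each permutation shifts the whole train
    by one uniform circular offset and recomputes the score against the
    unshifted kinematics.  Degenerate permutations (no rate variance over
    movement frames) score 0.  Returns ``(p, null, observed)``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        raise ValueError("cannot shuffle an empty spike train")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    span = kin.duration_s
    if 2 * min_shift_s >= span:
        min_shift_s = span / 4.0
    rate = instantaneous_rate(spike_times, kin)
    observed, _, reason = speed_score(rate, kin)
    if observed is None:
        raise ValueError(f"speed score undefined: {reason}")

    mov = kin.moving
    s_c = np.abs(kin.omega[mov]) - np.abs(kin.omega[mov]).mean()
    s_norm = np.sqrt(np.sum(s_c**2))

    t0 = float(kin.t[0])
    rel = spike_times - t0
    shifts = rng.uniform(min_shift_s, span - min_shift_s, n_perm)
    shifted = np.mod(rel[None, :] + shifts[:, None], span)
    fidx = np.minimum((shifted / kin.dt).astype(int), kin.t.size - 1)
    rows = np.broadcast_to(np.arange(n_perm)[:, None], fidx.shape)
    counts = np.bincount(
        (rows * kin.t.size + fidx).ravel(), minlength=n_perm * kin.t.size
    ).reshape(n_perm, kin.t.size)[:, mov].astype(float)

    c = counts - counts.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(c**2, axis=1)) * s_norm
    null = np.zeros(n_perm)
    nz = denom > 0
    null[nz] = (c @ s_c)[nz] / denom[nz]
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p), null, observed


def rest_vs_rotation_rates(
    spike_times: np.ndarray, kin: KinematicsSeries
) -> tuple[Optional[float], Optional[float], Optional[str]]:
    """Firing rate during rest and during rotation (Hz).

    Either value is ``None`` with a reason code when its epoch class is
    empty.  The two epoch durations always partition the session.
    """
    idx = frame_indices(spike_times, kin)
    ok = idx >= 0
    mov_spk = np.zeros(idx.size, dtype=bool)
    mov_spk[ok] = kin.moving[idx[ok]]
    t_mov, t_rest = kin.movement_time_s, kin.rest_time_s
    rate_rot = (np.sum(mov_spk) / t_mov) if t_mov > 0 else None
    rate_rest = (np.sum(ok & ~mov_spk) / t_rest) if t_rest > 0 else None
    reason = None
    if rate_rot is None or rate_rest is None:
        reason = "empty_epoch"
    return rate_rest, rate_rot, reason


def analyze_speed(
    spike_times: np.ndarray,
    kin: KinematicsSeries,
    n_perm: int = 1000,
    min_shift_s: float = 20.0,
    percentile: float = 95.0,
    seed: int | np.random.Generator | None = None,
) -> SpeedResult:
    """Full per-cell angular-speed analysis."""
    rate = instantaneous_rate(spike_times, kin)
    score, signed, reason = speed_score(rate, kin)
    rest, rot, rest_reason = rest_vs_rotation_rates(spike_times, kin)
    if score is None:
        return SpeedResult(
            None, None, None, None, rest, rot,
            reason=reason, rest_reason=rest_reason,
        )
    p, null, observed = shuffle_test_speed(
        spike_times, kin, n_perm=n_perm, min_shift_s=min_shift_s, seed=seed
    )
    return SpeedResult(
        speed_score=observed,
        speed_score_signed=signed,
        p_value=p,
        is_speed_modulated=bool(observed > np.percentile(null, percentile)),
        rate_rest_hz=rest,
        rate_rotation_hz=rot,
        rest_reason=rest_reason,
        null_distribution=null,
    )
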
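"""Head-direction tuning: tuning curves, HD index, shuffle test, stability.

The directional tuning curve divides movement-period spike counts by the
movement-period occupancy in each of 36 ten-degree bins.  The HD index is the
mean resultant (Rayleigh) vector length of the binned curve,

    R = | sum_i rate_i * exp(j * theta_i) | / sum_i rate_i,

which is 0 for a flat curve and 1 for a curve concentrated in a single bin.
Significance comes from a rigid-shift permutation test: the entire spike
sequence is circularly time-shifted by a uniform random offset (at least
``min_shift_s`` from zero), the index recomputed against the unshifted
kinematics, 1000 times; a cell is an HD cell when the observed index exceeds
the 95th percentile of that null, and a "strong" HD cell when additionally
the index exceeds 0.8 with p < 0.01.  Stability is the Pearson correlation
between tuning curves from the two halves of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinematics import KinematicsSeries
from .spikes import frame_indices

TWO_PI = 2.0 * np.pi

__all__ = [
    "TuningCurve",
    "HDResult",
    "StabilityResult",
    "ZeroOccupancyError",
    "compute_tuning_curve",
    "hd_index",
    "preferred_direction",
    "peak_bin_direction",
    "shuffle_test_hd",
    "split_half_stability",
    "classify_hd",
    "analyze_hd",
]


class ZeroOccupancyError(ValueError):
    """A direction bin was never visited during movement."""

    def __init__(self, bins):
        self.bins = list(bins)
        super().__init__(f"unvisited direction bins during movement: {self.bins}")


@dataclass(frozen=True)
class TuningCurve:
    """Occupancy-normalised directional firing-rate curve."""

    bin_centers: np.ndarray  #: radians
    occupancy: np.ndarray    #: seconds per bin (movement only)
    spike_counts: np.ndarray #: movement-period spikes per bin
    rates: np.ndarray        #: Hz

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def peak_rate(self) -> float:
        return float(self.rates.max())


@dataclass(frozen=True)
class StabilityResult:
    r: Optional[float]
    reason: Optional[str] = None


@dataclass
class HDResult:
    hd_index: float
    p_value: float
    preferred_dir_rad: float
    peak_dir_rad: float
    peak_rate_hz: float
    mean_rate_hz: float
    stability_r: Optional[float]
    stability_reason: Optional[str]
    is_hd: bool
    is_strong_hd: bool
    null_distribution: np.ndarray = field(repr=False)
    curve: TuningCurve = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# tuning curve and index
# ---------------------------------------------------------------------------

def _bin_of_frame(kin: KinematicsSeries, n_bins: int) -> np.ndarray:
    width = TWO_PI / n_bins
    return np.minimum((kin.theta / width).astype(int), n_bins - 1)


def compute_tuning_curve(
    spike_times: np.ndarray,
    kin: KinematicsSeries,
    n_bins: int = 36,
    check_coverage: bool = True,
) -> TuningCurve:
    """Movement-period tuning curve with per-bin occupancy normalisation.

    Each spike is assigned the head angle of its containing frame; occupancy
    is the summed frame duration per bin over movement frames.  Raises
    :class:`ZeroOccupancyError` listing the offending bins when any bin was
    never visited (the inclusion criterion requires all 36 bins visited).
    """
    if kin.moving is None:
        raise ValueError("movement mask not computed")
    dt = kin.dt
    bins = _bin_of_frame(kin, n_bins)
    occupancy = np.bincount(bins[kin.moving], minlength=n_bins) * dt

    idx = frame_indices(spike_times, kin)
    ok = idx >= 0
    mov = np.zeros(idx.size, dtype=bool)
    mov[ok] = kin.moving[idx[ok]]
    counts = np.bincount(bins[idx[mov]], minlength=n_bins).astype(float)

    if check_coverage and np.any(occupancy == 0):
        raise ZeroOccupancyError(np.nonzero(occupancy == 0)[0])
    rates = np.divide(
        counts, occupancy, out=np.zeros(n_bins), where=occupancy > 0
    )
    centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
    return TuningCurve(centers, occupancy, counts, rates)


def hd_index(curve: TuningCurve) -> float:
    """Mean resultant length of the rate-weighted bin-centre unit vectors."""
    rates = curve.rates
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    total = rates.sum()
    if total == 0:
        raise ValueError("all-zero tuning curve: HD index undefined for silent cells")
    z = np.sum(rates * np.exp(1j * curve.bin_centers))
    return float(np.abs(z) / total)


def preferred_direction(curve: TuningCurve) -> float:
    """Circular mean of the rate-weighted vector sum, in [0, 2*pi)."""
    total = curve.rates.sum()
    if total == 0:
        raise ValueError("all-zero tuning curve: preferred direction undefined")
    z = np.sum(curve.rates * np.exp(1j * curve.bin_centers))
    return float(np.mod(np.angle(z), TWO_PI))


def peak_bin_direction(curve: TuningCurve) -> float:
    """Centre of the maximal-rate bin (used for display ordering only)."""
    return float(curve.bin_centers[int(np.argmax(curve.rates))])


# ---------------------------------------------------------------------------
# shuffle test
# ---------------------------------------------------------------------------

def _null_indices_rigid_shift(
    spike_times: np.ndarray,
    kin: KinematicsSeries,
    shifts: np.ndarray,
    n_bins: int,
    occupancy: np.ndarray,
) -> np.ndarray:
    """HD index for each rigid circular shift of the whole spike train."""
    t0 = float(kin.t[0])
    span = kin.duration_s
    dt = kin.dt
    bins = _bin_of_frame(kin, n_bins)
    unit = np.exp(1j * (np.arange(n_bins) + 0.5) * TWO_PI / n_bins)

    rel = np.asarray(spike_times, dtype=float) - t0
    shifted = np.mod(rel[None, :] + shifts[:, None], span)
    fidx = np.minimum((shifted / dt).astype(int), kin.t.size - 1)
    mov = kin.moving[fidx]
    n_perm = shifts.size
    rows = np.broadcast_to(np.arange(n_perm)[:, None], fidx.shape)[mov]
    flat = rows * n_bins + bins[fidx[mov]]
    counts = np.bincount(flat, minlength=n_perm * n_bins).reshape(n_perm, n_bins)
    rates = counts / occupancy[None, :]
    den = rates.sum(axis=1)
    num = np.abs(rates @ unit)
    out = np.zeros(n_perm)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def shuffle_test_hd(
    spike_times: np.ndarray,
    kin: KinematicsSeries,
    n_perm: int = 1000,
    min_shift_s: float = 20.0,
    seed: int | np.random.Generator | None = None,
    n_bins: int = 36,
) -> tuple[float, np.ndarray, float]:
    """Rigid-shift permutation test of the HD index.

    Each permutation shifts all spikes by one uniform random offset with
    circular wraparound over the session and recomputes the index against the
    unshifted kinematics.  Returns ``(p_value, null_distribution, observed)``
    with ``p = (1 + #{null >= observed}) / (1 + n_perm)`` so p is never zero.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        raise ValueError("cannot shuffle an empty spike train")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for a 95th-percentile criterion")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    span = kin.duration_s
    if 2 * min_shift_s >= span:
        warnings.warn("min_shift_s >= half the session; reducing to span/4")
        min_shift_s = span / 4.0

    curve = compute_tuning_curve(spike_times, kin, n_bins=n_bins)
    observed = hd_index(curve)
    shifts = rng.uniform(min_shift_s, span - min_shift_s, n_perm)
    null = _null_indices_rigid_shift(
        spike_times, kin, shifts, n_bins, curve.occupancy
    )
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p), null, observed


# ---------------------------------------------------------------------------
# stability and classification
# ---------------------------------------------------------------------------

def split_half_stability(
    spike_times: np.ndarray, kin: KinematicsSeries, n_bins: int = 36
) -> StabilityResult:
    """Pearson r between tuning curves of the two halves of the recording.

    Requires every bin sampled during movement in both halves; otherwise an
    absent value with reason ``incomplete_half_coverage``.  The correlation is
    linear (not circular) between the two 36-bin rate vectors.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    mid = kin.t.size // 2
    halves = []
    for sl in (slice(0, mid), slice(mid, None)):
        sub = KinematicsSeries(
            t=kin.t[sl], theta=kin.theta[sl],
            theta_unwrapped=kin.theta_unwrapped[sl],
            x=kin.x[sl], y=kin.y[sl], center=kin.center,
            radius_cm=kin.radius_cm, omega=kin.omega[sl],
            alpha=kin.alpha[sl], lin_speed=kin.lin_speed[sl],
            moving=kin.moving[sl],
        )
        lo, hi = sub.t[0], sub.t[-1] + kin.dt
        s = spike_times[(spike_times >= lo) & (spike_times < hi)]
        try:
            halves.append(compute_tuning_curve(s, sub, n_bins=n_bins))
        except ZeroOccupancyError:
            return StabilityResult(None, "incomplete_half_coverage")
    a, b = halves[0].rates, halves[1].rates
    if np.std(a) == 0 or np.std(b) == 0:
        return StabilityResult(None, "zero_variance_half_curve")
    r = float(np.corrcoef(a, b)[0, 1])
    return StabilityResult(r)


def classify_hd(
    observed: float,
    p_value: float,
    null: np.ndarray,
    percentile: float = 95.0,
    strong_index: float = 0.8,
    strong_p: float = 0.01,
) -> tuple[bool, bool]:
    """HD-cell and strong-HD flags.

    ``is_hd`` when the observed index exceeds the null's 95th percentile;
    ``is_strong_hd`` when additionally index > 0.8 and p < 0.01.
    """
    is_hd = bool(observed > np.percentile(null, percentile))
    is_strong = bool(is_hd and observed > strong_index and p_value < strong_p)
    return is_hd, is_strong


def analyze_hd(
    spike_times: np.ndarray,
    kin: KinematicsSeries,
    n_bins: int = 36,
    n_perm: int = 1000,
    min_shift_s: float = 20.0,
    percentile: float = 95.0,
    strong_index: float = 0.8,
    strong_p: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> HDResult:
    """Full per-cell head-direction analysis."""
    curve = compute_tuning_curve(spike_times, kin, n_bins=n_bins)
    p, null, observed = shuffle_test_hd(
        spike_times, kin, n_perm=n_perm, min_shift_s=min_shift_s,
        seed=seed, n_bins=n_bins,
    )
    stab = split_half_stability(spike_times, kin, n_bins=n_bins)
    is_hd, is_strong = classify_hd(
        observed, p, null, percentile, strong_index, strong_p
    )
    mean_rate = curve.spike_counts.sum() / max(kin.movement_time_s, np.finfo(float).tiny)
    return HDResult(
        hd_index=observed,
        p_value=p,
        preferred_dir_rad=preferred_direction(curve),
        peak_dir_rad=peak_bin_direction(curve),
        peak_rate_hz=curve.peak_rate,
        mean_rate_hz=float(mean_rate),
        stability_r=stab.r,
        stability_reason=stab.reason,
        is_hd=is_hd,
        is_strong_hd=is_strong,
        null_distribution=null,
        curve=curve,
    )
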
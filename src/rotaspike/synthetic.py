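"""Synthetic passive-rotation sessions.

Emulates the study conditions of head-fixed passive-rotation recordings: an
LED on a platform rotated manually clockwise and counterclockwise (about
1.1 rad/s typical angular speed, accelerations around 1.3 rad/s^2, a handful
of direction inversions per session), interleaved with whole-block rest
epochs, tracked at 25 Hz.  Spike trains are drawn from an inhomogeneous
Poisson process whose intensity factorises into von Mises head-direction
tuning, sinusoidal theta modulation and a linear angular-speed term, thinned
against an explicit upper bound, with an absolute refractory period enforced
by deletion.  Waveforms are noise-free piecewise-linear biphasic templates
(narrow for fast-spiking cells, broad for principal cells) plus optional
Gaussian noise, sampled at 20 kHz.

Everything is deterministic given the seeds carried by the spec objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import i0

from .kinematics import (
    KinematicsSeries,
    TrackingTrace,
    compute_kinematics,
)

TWO_PI = 2.0 * np.pi

__all__ = [
    "SessionSpec",
    "CellSpec",
    "WaveformTemplate",
    "SyntheticSession",
    "ScheduleError",
    "generate_rotation_trajectory",
    "generate_spike_train",
    "generate_waveform",
    "generate_waveform_snippets",
    "generate_session",
    "write_session",
]


class ScheduleError(ValueError):
    """Raised when the requested rotation schedule cannot fit the session."""


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one simulated passive-rotation session.

    Defaults follow the recording conditions the analyses assume: 25 Hz
    video frames, around seven direction inversions per session, a typical
    angular speed of 1.1 rad/s with 1.3 rad/s^2 ramps, and a fifth of the
    session spent at rest.  The LED radius (10 cm) only matters for the
    conversion between angular and linear speed at the 1 cm/s rest cutoff.
    """

    duration_s: float = 300.0
    frame_rate_hz: float = 25.0
    led_radius_cm: float = 10.0
    n_inversions: int = 7
    target_angular_speed_rad_s: float = 1.1
    target_accel_rad_s2: float = 1.3
    rest_fraction: float = 0.2
    speed_jitter: float = 0.2  #: CV of smooth within-segment speed fluctuation
    noise_cm: float = 0.0      #: isotropic Gaussian tracking noise on x, y
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.frame_rate_hz <= 0 or self.led_radius_cm <= 0:
            raise ValueError("duration_s, frame_rate_hz, led_radius_cm must be > 0")
        if not (0.0 <= self.rest_fraction <= 1.0):
            raise ValueError("rest_fraction must lie in [0, 1]")
        if self.n_inversions < 0:
            raise ValueError("n_inversions must be >= 0")
        if self.target_angular_speed_rad_s <= 0 or self.target_accel_rad_s2 <= 0:
            raise ValueError("target speed and acceleration must be > 0")


@dataclass(frozen=True)
class CellSpec:
    """Firing model of one simulated cell.

    The intensity on the frame grid is::

        lam(t) = base_rate_hz
                 * exp(kappa * cos(theta(t) - preferred_dir_rad)) / I0(kappa)
                 * (1 + theta_depth * cos(2*pi*theta_freq_hz*t))
                 * max(0, 1 + speed_gain * |omega(t)| / base_rate_hz)

    The von Mises factor is normalised by I0(kappa) so the mean rate over a
    uniform sweep of directions stays near ``base_rate_hz``; the speed term
    is floored at zero so the intensity is never negative.
    """

    base_rate_hz: float = 5.0
    kappa: float = 0.0
    preferred_dir_rad: float = 0.0
    theta_freq_hz: Optional[float] = None   #: Hz in [4, 12], or None for none
    theta_depth: float = 0.0
    speed_gain: float = 0.0                 #: Hz per rad/s, signed
    refractory_ms: float = 2.0
    celltype_label: str = "principal"       #: {"principal", "fs"}
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0 or self.base_rate_hz < 0:
            raise ValueError("kappa and base_rate_hz must be >= 0")
        if not (0.0 <= self.theta_depth <= 1.0):
            raise ValueError("theta_depth must lie in [0, 1]")
        if self.theta_freq_hz is not None and not (4.0 <= self.theta_freq_hz <= 12.0):
            raise ValueError("theta_freq_hz must lie in [4, 12]")
        if self.celltype_label not in ("principal", "fs"):
            raise ValueError("celltype_label must be 'principal' or 'fs'")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _partition(total: float, n: int, floor: float, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into n parts, each >= floor, with ~30% random jitter."""
    if n == 0:
        return np.zeros(0)
    w = rng.uniform(0.7, 1.3, n)
    return floor + (total - n * floor) * w / w.sum()


def generate_rotation_trajectory(spec: SessionSpec) -> TrackingTrace:
    """Simulate the LED trace of one passive-rotation session.

    The angular-velocity profile is a sequence of ``n_inversions + 1``
    rotation segments of alternating sign, each a trapezoid (ramp at the
    target acceleration, cruise near the target speed, ramp down), separated
    and flanked by whole-block rest epochs totalling ``rest_fraction`` of the
    session.  The head angle is the integral of that profile; the LED sits at
    ``led_radius_cm`` from a fixed centre.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate_hz
    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    t = np.arange(n_frames) * dt

    n_seg = spec.n_inversions + 1
    movement_time = spec.duration_s * (1.0 - spec.rest_fraction)
    rest_time = spec.duration_s - movement_time
    t_ramp = spec.target_angular_speed_rad_s / spec.target_accel_rad_s2
    min_seg = 2.0 * t_ramp + 0.2  # ramps plus a minimal cruise
    if n_seg * min_seg > movement_time:
        raise ScheduleError(
            f"{spec.n_inversions} inversions need at least "
            f"{n_seg * min_seg:.1f} s of movement; only {movement_time:.1f} s available"
        )

    seg_dur = _partition(movement_time, n_seg, min_seg, rng)
    rest_dur = _partition(rest_time, n_seg + 1, 0.0, rng)

    # breakpoints of the piecewise-linear omega(t)
    sign = rng.choice([-1.0, 1.0])
    bp_t, bp_w = [0.0], [0.0]
    clock = 0.0
    for i in range(n_seg):
        clock += rest_dur[i]
        cruise = seg_dur[i] - 2.0 * t_ramp
        s = sign * spec.target_angular_speed_rad_s
        for tt, ww in (
            (clock, 0.0),
            (clock + t_ramp, s),
            (clock + t_ramp + cruise, s),
            (clock + seg_dur[i], 0.0),
        ):
            bp_t.append(tt)
            bp_w.append(ww)
        clock += seg_dur[i]
        sign = -sign
    bp_t.append(spec.duration_s)
    bp_w.append(0.0)

    omega = np.interp(t, bp_t, bp_w)
    if spec.speed_jitter > 0:
        # manual rotation is not constant-speed: multiply by a smooth,
        # sign-preserving fluctuation (~0.5 s correlation time)
        from scipy.ndimage import gaussian_filter1d

        noise = gaussian_filter1d(
            rng.normal(0.0, 1.0, n_frames), sigma=0.5 * spec.frame_rate_hz,
            mode="reflect",
        )
        sd = noise.std()
        if sd > 0:
            omega = omega * np.clip(
                1.0 + spec.speed_jitter * noise / sd, 0.2, None
            )
    theta0 = rng.uniform(0.0, TWO_PI)
    theta = theta0 + np.concatenate(([0.0], cumulative_trapezoid(omega, t)))

    x = spec.led_radius_cm * np.cos(theta)
    y = spec.led_radius_cm * np.sin(theta)
    if spec.noise_cm > 0:
        x = x + rng.normal(0.0, spec.noise_cm, n_frames)
        y = y + rng.normal(0.0, spec.noise_cm, n_frames)
    return TrackingTrace(t, x, y)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _intensity_on_grid(kin: KinematicsSeries, cell: CellSpec) -> np.ndarray:
    """Evaluate lam(t) of :class:`CellSpec` on the kinematics frame grid."""
    lam = np.full(kin.t.size, cell.base_rate_hz, dtype=float)
    if cell.base_rate_hz == 0.0:
        return lam
    if cell.kappa > 0:
        lam = lam * np.exp(
            cell.kappa * np.cos(kin.theta - cell.preferred_dir_rad)
        ) / i0(cell.kappa)
    if cell.theta_freq_hz is not None and cell.theta_depth > 0:
        lam = lam * (1.0 + cell.theta_depth * np.cos(TWO_PI * cell.theta_freq_hz * kin.t))
    if cell.speed_gain != 0.0:
        lam = lam * np.maximum(
            0.0, 1.0 + cell.speed_gain * np.abs(kin.omega) / cell.base_rate_hz
        )
    return lam


def generate_spike_train(kin: KinematicsSeries, cell: CellSpec) -> np.ndarray:
    """Inhomogeneous-Poisson spike train by thinning.

    The intensity is evaluated per video frame (piecewise constant); the
    thinning bound is its maximum over the grid.  Candidate spikes are drawn
    homogeneously at the bound and accepted with probability lam(frame)/bound,
    so no spike can fall in a frame where the intensity is zero.  The absolute
    refractory period is enforced afterwards by deleting any spike closer than
    ``refractory_ms`` to the previously kept one.  Returns sorted, strictly
    increasing spike times in seconds.
    """
    if kin.omega is None:
        raise ValueError("kinematics must include angular velocity")
    rng = np.random.default_rng(cell.seed)
    t0 = float(kin.t[0])
    span = kin.duration_s
    if span <= 0:
        raise ValueError("kinematics must cover a positive time span")
    lam = _intensity_on_grid(kin, cell)
    lam_max = float(lam.max(initial=0.0))
    if not np.isfinite(lam_max):
        raise ValueError("non-finite thinning bound")
    if lam_max == 0.0:
        return np.zeros(0)

    n_cand = rng.poisson(lam_max * span)
    cand = np.sort(rng.uniform(t0, t0 + span, n_cand))
    frame = np.minimum(((cand - t0) / kin.dt).astype(int), kin.t.size - 1)
    keep = rng.uniform(0.0, lam_max, n_cand) < lam[frame]
    times = cand[keep]

    refr = cell.refractory_ms / 1000.0
    if refr > 0 and times.size > 1:
        kept = [times[0]]
        for s in times[1:]:
            if s - kept[-1] >= refr:
                kept.append(s)
        times = np.asarray(kept)
    return times


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformTemplate:
    """Piecewise-linear biphasic template geometry (all times in ms).

    The positive peak is a triangle of base ``peak_width_ms`` and amplitude 1;
    the trough is a triangle of base ``trough_width_ms`` and depth
    ``negativity`` whose apex lags the peak apex by ``peak_to_trough_ms``.
    Closed-form feature values: half-width = peak_width_ms / 2, peak-to-trough
    = peak_to_trough_ms, negativity amplitude = negativity.
    """

    peak_width_ms: float
    peak_to_trough_ms: float
    trough_width_ms: float
    negativity: float

    @classmethod
    def for_celltype(cls, label: str) -> "WaveformTemplate":
        if label == "fs":
            return cls(peak_width_ms=0.2, peak_to_trough_ms=0.25,
                       trough_width_ms=0.3, negativity=0.6)
        return cls(peak_width_ms=0.4, peak_to_trough_ms=0.8,
                   trough_width_ms=0.8, negativity=0.5)


def generate_waveform(
    cell: CellSpec,
    n_samples: int = 64,
    sampling_rate_hz: float = 20_000.0,
    alignment: int = 20,
    template: WaveformTemplate | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One waveform snippet for the cell's type, sampled at 20 kHz.

    The noise-free template is exactly piecewise linear with the geometry of
    :class:`WaveformTemplate`; the positive apex lands on sample ``alignment``.
    """
    tpl = template or WaveformTemplate.for_celltype(cell.celltype_label)
    if rng is None:
        rng = np.random.default_rng(cell.seed)
    ms = np.arange(n_samples) / sampling_rate_hz * 1000.0
    apex = ms[alignment]
    hw = tpl.peak_width_ms / 2.0
    trough_apex = apex + tpl.peak_to_trough_ms
    tw = tpl.trough_width_ms / 2.0
    bp_t = [
        ms[0] - 1.0,
        apex - hw, apex, apex + hw,
        trough_apex - tw, trough_apex, trough_apex + tw,
        ms[-1] + 1.0,
    ]
    bp_v = [0.0, 0.0, 1.0, 0.0, 0.0, -tpl.negativity, 0.0, 0.0]
    if apex + hw > trough_apex - tw:
        raise ValueError("peak and trough lobes overlap; widen peak_to_trough_ms")
    w = np.interp(ms, bp_t, bp_v)
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, n_samples)
    return w


def generate_waveform_snippets(
    cell: CellSpec,
    n_snippets: int,
    n_samples: int = 64,
    sampling_rate_hz: float = 20_000.0,
    alignment: int = 20,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Matrix of noisy snippets (n_snippets x n_samples) for one cell."""
    rng = np.random.default_rng(cell.seed)
    tpl = WaveformTemplate.for_celltype(cell.celltype_label)
    clean = generate_waveform(
        cell, n_samples, sampling_rate_hz, alignment, tpl, noise_sd=0.0
    )
    return clean[None, :] + rng.normal(0.0, noise_sd, (n_snippets, n_samples))


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSession:
    spec: SessionSpec
    trace: TrackingTrace
    kin: KinematicsSeries
    cells: dict[str, CellSpec]
    spikes: dict[str, np.ndarray]
    waveforms: dict[str, np.ndarray]
    layers: dict[str, str] = field(default_factory=dict)


def generate_session(
    spec: SessionSpec,
    cells: Sequence[CellSpec] | dict[str, CellSpec],
    layers: dict[str, str] | None = None,
    n_snippets: int = 30,
    waveform_noise_sd: float = 0.05,
) -> SyntheticSession:
    """Trajectory plus spike trains and waveform snippets for a cohort.

    Spikes are generated from the *analysed* kinematics of the simulated
    trace (smoothed coordinates, fitted centre), so the generative direction
    signal and the analysis direction signal match up to the smoothing the
    analysis itself applies.
    """
    if not isinstance(cells, dict):
        cells = {f"cell{i:03d}": c for i, c in enumerate(cells)}
    trace = generate_rotation_trajectory(spec)
    kin = compute_kinematics(trace)
    spikes = {cid: generate_spike_train(kin, c) for cid, c in cells.items()}
    waveforms = {
        cid: generate_waveform_snippets(
            c, n_snippets, noise_sd=waveform_noise_sd
        )
        for cid, c in cells.items()
    }
    return SyntheticSession(
        spec=spec, trace=trace, kin=kin, cells=dict(cells),
        spikes=spikes, waveforms=waveforms, layers=dict(layers or {}),
    )


def write_session(session: SyntheticSession, outdir: str | Path) -> Path:
    """Write tracking, spikes, waveforms, spec and a JSON manifest.

    Formats: tracking CSV (t_s,x_cm,y_cm); one spike CSV per cell (column
    ``t_s``); one waveform CSV matrix per cell (snippets x samples); the
    session spec as key=value text; manifest.json echoing paths and seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session.trace.to_csv(outdir / "tracking.csv")
    manifest: dict = {
        "tracking": "tracking.csv",
        "spec": "session_spec.txt",
        "seed": session.spec.seed,
        "cells": {},
    }
    spec = session.spec
    lines = [f"{k}={getattr(spec, k)}" for k in (
        "duration_s", "frame_rate_hz", "led_radius_cm", "n_inversions",
        "target_angular_speed_rad_s", "target_accel_rad_s2", "rest_fraction",
        "speed_jitter", "noise_cm", "seed",
    )]
    (outdir / "session_spec.txt").write_text("\n".join(lines) + "\n")
    for cid in sorted(session.cells):
        spike_file = f"spikes_{cid}.csv"
        wf_file = f"waveforms_{cid}.csv"
        pd.DataFrame({"t_s": session.spikes[cid]}).to_csv(
            outdir / spike_file, index=False
        )
        np.savetxt(outdir / wf_file, session.waveforms[cid], delimiter=",")
        manifest["cells"][cid] = {
            "spikes": spike_file,
            "waveforms": wf_file,
            "seed": session.cells[cid].seed,
            "celltype": session.cells[cid].celltype_label,
            "layer": session.layers.get(cid, "unknown"),
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir / "manifest.json"
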
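"""Spike-to-frame alignment shared by the tuning, rhythmicity and speed code.

Every analysis assigns a spike the kinematic state of its containing video
frame: frame i covers [t[i], t[i] + dt).  Spikes outside the tracked span are
dropped; movement gating uses the frame's ``moving`` flag.
"""

from __future__ import annotations

import numpy as np

from .kinematics import KinematicsSeries

__all__ = ["frame_indices", "movement_spikes"]


def frame_indices(spike_times: np.ndarray, kin: KinematicsSeries) -> np.ndarray:
    """Index of the containing frame for each spike; -1 if outside the session."""
    s = np.asarray(spike_times, dtype=float)
    dt = kin.dt
    t0 = float(kin.t[0])
    idx = np.floor((s - t0) / dt).astype(int)
    idx[(s < t0) | (idx >= kin.t.size)] = -1
    return idx


def movement_spikes(spike_times: np.ndarray, kin: KinematicsSeries) -> np.ndarray:
    """Spike times falling in movement frames (the only ones analysed)."""
    if kin.moving is None:
        raise ValueError("movement mask not computed")
    s = np.asarray(spike_times, dtype=float)
    idx = frame_indices(s, kin)
    ok = idx >= 0
    keep = np.zeros(s.size, dtype=bool)
    keep[ok] = kin.moving[idx[ok]]
    return s[keep]
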
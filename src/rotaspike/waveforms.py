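"""Spike waveform features, bursting index, and FS classification.

Waveform snippets are sampled at 20 kHz with the positive peak aligned.
Features follow the standard extracellular conventions:

* peak-to-trough time: from the positive maximum to the subsequent minimum
  (the spike-width measure used for fast-spiking classification),
* half-width: width of the positive peak at half its amplitude above
  baseline (baseline = mean of the leading quarter of the snippet), with
  linear interpolation at the half-amplitude crossings,
* negativity amplitude: trough depth as a fraction of peak amplitude.

The bursting index is the fraction of spikes whose *preceding* inter-spike
interval is below 6 ms (the first spike has no preceding interval and never
counts).  A cell is classified fast-spiking (FS) when its peak-to-trough time
is below the width threshold AND its firing rate is above the rate threshold;
the default thresholds (0.4 ms, 5 Hz) are configuration values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "WaveformFeatures",
    "average_waveform",
    "extract_features",
    "bursting_index",
    "classify_fs",
]


@dataclass
class WaveformFeatures:
    peak_to_trough_ms: Optional[float]
    half_width_ms: Optional[float]
    negativity_amp: Optional[float]   #: |trough| / peak, unitless
    peak_amp: float
    baseline: float
    reason: Optional[str] = None


def average_waveform(snippets: np.ndarray) -> np.ndarray:
    """Pointwise mean of peak-aligned snippets (n_snippets x n_samples)."""
    w = np.asarray(snippets, dtype=float)
    if w.ndim == 1:
        return w.copy()
    if w.ndim != 2 or w.shape[0] < 1:
        raise ValueError("snippets must be a non-empty 2-D matrix")
    return w.mean(axis=0)


def _interp_crossing(x: np.ndarray, i: int, level: float) -> float:
    """Sub-sample index where x crosses `level` between samples i and i+1."""
    d = x[i + 1] - x[i]
    if d == 0:
        return float(i)
    return i + (level - x[i]) / d


def extract_features(
    samples: np.ndarray,
    sampling_rate_hz: float = 20_000.0,
    baseline_frac: float = 0.25,
) -> WaveformFeatures:
    """Shape features of an averaged waveform.

    Durations come out in ms; amplitudes are baseline-referenced.  A
    monophasic waveform (no post-peak excursion below baseline) yields absent
    trough-dependent features with reason ``monophasic``.
    """
    w = np.asarray(samples, dtype=float)
    if w.ndim != 1 or w.size < 4:
        raise ValueError("waveform must be a 1-D array of at least 4 samples")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform contains non-finite samples")
    n_base = max(1, int(round(baseline_frac * w.size)))
    baseline = float(w[:n_base].mean())
    peak_i = int(np.argmax(w))
    peak_amp = float(w[peak_i] - baseline)
    if peak_amp <= 0:
        raise ValueError("no identifiable positive peak above baseline")
    ms_per_sample = 1000.0 / sampling_rate_hz

    # half-width of the positive peak, sub-sample interpolated
    half = baseline + peak_amp / 2.0
    left = None
    for i in range(peak_i - 1, -1, -1):
        if w[i] <= half:
            left = _interp_crossing(w, i, half)
            break
    right = None
    for i in range(peak_i, w.size - 1):
        if w[i + 1] <= half:
            right = _interp_crossing(w, i, half)
            break
    half_width = (
        (right - left) * ms_per_sample if left is not None and right is not None
        else None
    )

    post = w[peak_i:]
    trough_rel = int(np.argmin(post))
    trough_i = peak_i + trough_rel
    trough_amp = float(baseline - w[trough_i])
    if trough_rel == 0 or trough_amp <= 0:
        return WaveformFeatures(
            None, half_width, None, peak_amp, baseline, reason="monophasic"
        )
    return WaveformFeatures(
        peak_to_trough_ms=(trough_i - peak_i) * ms_per_sample,
        half_width_ms=half_width,
        negativity_amp=trough_amp / peak_amp,
        peak_amp=peak_amp,
        baseline=baseline,
    )


def bursting_index(spike_times: np.ndarray, isi_thresh_s: float = 0.006) -> float:
    """Fraction of spikes whose preceding ISI is below the burst threshold."""
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        raise ValueError("bursting index undefined for an empty spike train")
    if t.size == 1:
        return 0.0
    return float(np.sum(np.diff(t) < isi_thresh_s) / t.size)


def classify_fs(
    peak_to_trough_ms: Optional[float],
    mean_rate_hz: float,
    width_threshold_ms: float = 0.4,
    rate_threshold_hz: float = 5.0,
) -> Optional[bool]:
    """Fast-spiking flag: narrow spike AND high rate; None if width absent."""
    if peak_to_trough_ms is None:
        return None
    return bool(
        peak_to_trough_ms < width_threshold_ms and mean_rate_hz > rate_threshold_hz
    )
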
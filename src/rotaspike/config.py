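"""Analysis configuration.

Every threshold used anywhere in the pipeline lives in one declarative
:class:`AnalysisConfig` so that a session report is fully determined by
(inputs, config, seed).  The defaults are the values standard in the
head-direction literature: 36 direction bins (10 deg), a 600 ms boxcar on the
LED coordinates, a 1 cm/s linear-speed cutoff separating rest from rotation,
10 ms autocorrelogram bins, a 4-12 Hz theta band referenced to 1-50 Hz,
a >20-spike inclusion criterion for rhythmicity, a 6 ms burst ISI, 1000
permutations against a 95th-percentile criterion, and the HD index > 0.8 with
p < 0.01 "strong HD" conjunction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    # -- kinematics --------------------------------------------------------
    smooth_window_s: float = 0.6      #: boxcar window on LED x/y (s)
    speed_cutoff_cm_s: float = 1.0    #: linear speed separating rest from movement
    led_radius_cm: float = 10.0       #: LED distance from the rotation centre
    hd_offset_rad: float = 0.0        #: fixed LED-to-head-direction offset
    inversion_eps_rad: float = 1e-4   #: dead-band suppressing rest chatter

    # -- head-direction tuning --------------------------------------------
    n_bins: int = 36                  #: 10-degree direction bins
    n_perm: int = 1000                #: permutations per shuffle test
    min_shift_s: float = 20.0         #: minimum rigid time-shift of the spike train
    percentile: float = 95.0          #: null-distribution significance percentile
    strong_hd_index: float = 0.8      #: "strong HD" index threshold
    strong_hd_p: float = 0.01         #: "strong HD" p-value threshold

    # -- theta rhythmicity -------------------------------------------------
    acg_bin_s: float = 0.010          #: autocorrelogram bin width (s)
    acg_max_lag_s: float = 0.5        #: autocorrelogram half-window (s)
    theta_band_hz: tuple[float, float] = (4.0, 12.0)
    broad_band_hz: tuple[float, float] = (1.0, 50.0)
    pad_factor: int = 4               #: FFT zero-padding for peak localisation
    min_theta_spikes: int = 20        #: inclusion criterion (strictly more required)
    weak_theta_index: float = 5.0     #: descriptive "weak rhythmicity" flag level

    # -- spike features ----------------------------------------------------
    burst_isi_s: float = 0.006        #: ISI defining the bursting-index numerator
    fs_width_ms: float = 0.4          #: FS classification: peak-to-trough below this
    fs_rate_hz: float = 5.0           #: FS classification: movement rate above this
    baseline_frac: float = 0.25       #: leading fraction of a snippet used as baseline

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["theta_band_hz"] = list(self.theta_band_hz)
        d["broad_band_hz"] = list(self.broad_band_hz)
        return d

    def hash(self) -> str:
        """Stable content hash recorded in session manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("theta_band_hz", "broad_band_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
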
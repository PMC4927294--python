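"""Session orchestration: the model/results layer over the analysis modules.

:class:`RotationSession` is built from a tracking trace plus per-cell spike
trains (and optional waveform snippets and layer labels); ``fit()`` runs the
whole chain — kinematics, head-direction tuning with its shuffle null, theta
rhythmicity, angular-speed modulation, waveform features — and returns a
:class:`SessionResults` carrying one :class:`CellReport` per cell, a tabular
``summary()``, layer-level group comparisons and a deterministic JSON export.
Per-cell failures of an analysis's inclusion criteria (silent cell, unvisited
direction bins, too few spikes) are recorded as explicit reason codes; the
other statistics of that cell are still computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import AnalysisConfig
from .hd import HDResult, ZeroOccupancyError, analyze_hd
from .kinematics import (
    KinematicsSeries,
    SessionKinematicsSummary,
    TrackingTrace,
    compute_kinematics,
    summarize_kinematics,
)
from .rhythmicity import ThetaResult, analyze_theta
from .speed import SpeedResult, analyze_speed
from .spikes import frame_indices, movement_spikes
from .stats import GroupComparison, fisher_exact, mann_whitney
from .waveforms import (
    WaveformFeatures,
    average_waveform,
    bursting_index,
    classify_fs,
    extract_features,
)

__all__ = [
    "CellData",
    "CellReport",
    "RotationSession",
    "SessionResults",
    "layer_summary",
    "composition_table",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class CellData:
    """Input bundle for one cell."""

    cell_id: str
    spike_times: np.ndarray
    waveforms: Optional[np.ndarray] = None  #: snippets x samples, peak-aligned
    layer: str = "unknown"                  #: {"L2", "L3", "deep", "unknown"}
    waveform_sampling_hz: float = 20_000.0


@dataclass
class CellReport:
    """All per-cell statistics, with explicit reasons for absent ones."""

    cell_id: str
    layer: str
    n_spikes: int
    n_movement_spikes: int
    mean_rate_hz: float                #: whole-session rate
    mean_rate_movement_hz: Optional[float]
    bursting_index: Optional[float]
    hd: Optional[HDResult]
    hd_reason: Optional[str]
    theta: Optional[ThetaResult]
    speed: Optional[SpeedResult]
    speed_reason: Optional[str]
    features: Optional[WaveformFeatures]
    features_reason: Optional[str]
    is_fs: Optional[bool]

    def flags(self) -> dict:
        return {
            "hd": bool(self.hd.is_hd) if self.hd else None,
            "strong_hd": bool(self.hd.is_strong_hd) if self.hd else None,
            "theta_rhythmic": (
                self.theta.is_theta_rhythmic if self.theta else None
            ),
            "speed_modulated": (
                self.speed.is_speed_modulated if self.speed else None
            ),
            "fs": self.is_fs,
        }

    def to_dict(self) -> dict:
        hd = self.hd
        th = self.theta
        sp = self.speed
        ft = self.features
        return {
            "cell_id": self.cell_id,
            "layer": self.layer,
            "n_spikes": self.n_spikes,
            "n_movement_spikes": self.n_movement_spikes,
            "mean_rate_hz": self.mean_rate_hz,
            "mean_rate_movement_hz": self.mean_rate_movement_hz,
            "bursting_index": self.bursting_index,
            "hd_index": hd.hd_index if hd else None,
            "hd_p": hd.p_value if hd else None,
            "preferred_dir_deg": (
                float(np.degrees(hd.preferred_dir_rad)) if hd else None
            ),
            "peak_rate_hz": hd.peak_rate_hz if hd else None,
            "stability_r": hd.stability_r if hd else None,
            "stability_reason": hd.stability_reason if hd else None,
            "hd_reason": self.hd_reason,
            "theta_index": th.theta_index if th else None,
            "theta_p": th.p_value if th else None,
            "theta_peak_freq_hz": th.peak_freq_hz if th else None,
            "theta_reason": th.reason if th else "not_computed",
            "speed_score": sp.speed_score if sp else None,
            "speed_score_signed": sp.speed_score_signed if sp else None,
            "speed_p": sp.p_value if sp else None,
            "rate_rest_hz": sp.rate_rest_hz if sp else None,
            "rate_rotation_hz": sp.rate_rotation_hz if sp else None,
            "speed_reason": self.speed_reason,
            "peak_to_trough_ms": ft.peak_to_trough_ms if ft else None,
            "half_width_ms": ft.half_width_ms if ft else None,
            "negativity_amp": ft.negativity_amp if ft else None,
            "features_reason": self.features_reason,
            "flags": self.flags(),
        }


class RotationSession:
    """Model object: one passive-rotation session with its recorded cells.

    Parameters
    ----------
    tracking : TrackingTrace
        Raw LED positions per video frame.
    cells : sequence of CellData
        Sorted spike times (and optional waveform snippets) per cell.
    config : AnalysisConfig, optional
        All analysis thresholds; defaults match the standard values.
    """

    def __init__(
        self,
        tracking: TrackingTrace,
        cells: Sequence[CellData],
        config: AnalysisConfig | None = None,
    ):
        self.tracking = tracking
        self.cells = list(cells)
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell ids")
        self.config = config or AnalysisConfig()

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        tracking_file: str | Path,
        spike_files: Mapping[str, str | Path],
        waveform_files: Mapping[str, str | Path] | None = None,
        layers: Mapping[str, str] | None = None,
        config: AnalysisConfig | None = None,
    ) -> "RotationSession":
        """Build a session from tracking/spike/waveform CSV files."""
        tracking = TrackingTrace.from_csv(tracking_file)
        waveform_files = waveform_files or {}
        layers = layers or {}
        cells = []
        for cid, path in spike_files.items():
            spikes = pd.read_csv(path)["t_s"].to_numpy(dtype=float)
            wf = None
            if cid in waveform_files:
                wf = np.loadtxt(waveform_files[cid], delimiter=",", ndmin=2)
            cells.append(
                CellData(cid, spikes, wf, layers.get(cid, "unknown"))
            )
        return cls(tracking, cells, config=config)

    @classmethod
    def from_synthetic(cls, session, config: AnalysisConfig | None = None):
        """Build from a :class:`rotaspike.synthetic.SyntheticSession`."""
        cells = [
            CellData(
                cid,
                session.spikes[cid],
                session.waveforms.get(cid),
                session.layers.get(cid, "unknown"),
            )
            for cid in sorted(session.cells)
        ]
        return cls(session.trace, cells, config=config)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0, n_perm: int | None = None) -> "SessionResults":
        """Run every per-cell analysis; returns a :class:`SessionResults`.

        ``seed`` controls all shuffle randomness; per-cell substreams are
        spawned from it so reports are reproducible cell by cell.  ``n_perm``
        overrides the configured permutation count (e.g. for quick looks).
        """
        cfg = self.config if n_perm is None else self.config.replace(n_perm=n_perm)
        kin = compute_kinematics(
            self.tracking,
            window_s=cfg.smooth_window_s,
            cutoff_cm_s=cfg.speed_cutoff_cm_s,
            offset_rad=cfg.hd_offset_rad,
        )
        kin_summary = summarize_kinematics(kin, eps_rad=cfg.inversion_eps_rad)
        streams = np.random.SeedSequence(seed).spawn(len(self.cells))
        reports = [
            self._fit_cell(cell, kin, cfg, np.random.default_rng(ss))
            for cell, ss in zip(self.cells, streams)
        ]
        return SessionResults(reports, kin, kin_summary, cfg, seed)

    def _fit_cell(
        self,
        cell: CellData,
        kin: KinematicsSeries,
        cfg: AnalysisConfig,
        rng: np.random.Generator,
    ) -> CellReport:
        spikes = np.sort(np.asarray(cell.spike_times, dtype=float))
        mov = movement_spikes(spikes, kin)
        duration = kin.duration_s
        mean_rate = spikes.size / duration
        t_mov = kin.movement_time_s
        mean_rate_mov = mov.size / t_mov if t_mov > 0 else None
        burst = bursting_index(spikes, cfg.burst_isi_s) if spikes.size else None

        hd = hd_reason = None
        speed = speed_reason = None
        if spikes.size == 0:
            hd_reason = speed_reason = "silent_cell"
            theta = ThetaResult(
                None, None, None, None, None, 0, reason="silent_cell"
            )
        else:
            try:
                hd = analyze_hd(
                    spikes, kin, n_bins=cfg.n_bins, n_perm=cfg.n_perm,
                    min_shift_s=cfg.min_shift_s, percentile=cfg.percentile,
                    strong_index=cfg.strong_hd_index, strong_p=cfg.strong_hd_p,
                    seed=rng,
                )
            except ZeroOccupancyError as err:
                hd_reason = f"unvisited_bins:{','.join(map(str, err.bins))}"
            except ValueError as err:
                hd_reason = str(err)
            theta = analyze_theta(
                mov, duration, n_perm=cfg.n_perm, seed=rng,
                min_spikes=cfg.min_theta_spikes,
                weak_threshold=cfg.weak_theta_index,
                percentile=cfg.percentile, t0=float(kin.t[0]),
                bin_s=cfg.acg_bin_s, max_lag_s=cfg.acg_max_lag_s,
                theta_band_hz=cfg.theta_band_hz,
                broad_band_hz=cfg.broad_band_hz, pad_factor=cfg.pad_factor,
            )
            speed = analyze_speed(
                spikes, kin, n_perm=cfg.n_perm, min_shift_s=cfg.min_shift_s,
                percentile=cfg.percentile, seed=rng,
            )
            speed_reason = speed.reason

        features = features_reason = None
        is_fs = None
        if cell.waveforms is not None and np.size(cell.waveforms):
            try:
                avg = average_waveform(cell.waveforms)
                features = extract_features(
                    avg, cell.waveform_sampling_hz, cfg.baseline_frac
                )
                features_reason = features.reason
            except ValueError as err:
                features_reason = str(err)
            if features is not None and mean_rate_mov is not None:
                is_fs = classify_fs(
                    features.peak_to_trough_ms, mean_rate_mov,
                    cfg.fs_width_ms, cfg.fs_rate_hz,
                )
        else:
            features_reason = "no_waveforms"

        return CellReport(
            cell_id=cell.cell_id,
            layer=cell.layer,
            n_spikes=int(spikes.size),
            n_movement_spikes=int(mov.size),
            mean_rate_hz=float(mean_rate),
            mean_rate_movement_hz=(
                float(mean_rate_mov) if mean_rate_mov is not None else None
            ),
            bursting_index=burst,
            hd=hd,
            hd_reason=hd_reason,
            theta=theta,
            speed=speed,
            speed_reason=speed_reason,
            features=features,
            features_reason=features_reason,
            is_fs=is_fs,
        )


class SessionResults:
    """Fitted per-cell statistics plus session-level summaries."""

    def __init__(
        self,
        reports: list[CellReport],
        kin: KinematicsSeries,
        kin_summary: SessionKinematicsSummary,
        config: AnalysisConfig,
        seed: int,
    ):
        self.reports = reports
        self.kinematics = kin
        self.kinematics_summary = kin_summary
        self.config = config
        self.seed = seed

    def table(self) -> pd.DataFrame:
        """One row per cell — the session-level analogue of a source-data table."""
        rows = []
        for r in self.reports:
            d = r.to_dict()
            d.update({f"is_{k}": v for k, v in d.pop("flags").items()})
            rows.append(d)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Readable per-cell summary of the headline statistics."""
        cols = [
            "cell_id", "layer", "n_spikes", "mean_rate_hz", "hd_index",
            "hd_p", "stability_r", "theta_index", "theta_p", "speed_score",
            "speed_p", "bursting_index", "peak_to_trough_ms", "is_hd",
            "is_strong_hd", "is_theta_rhythmic", "is_speed_modulated", "is_fs",
        ]
        df = self.table()
        cols = [c for c in cols if c in df.columns]
        ks = self.kinematics_summary
        head = (
            f"Passive-rotation session: {len(self.reports)} cells, "
            f"{self.kinematics.duration_s:.0f} s "
            f"({ks.movement_time_s:.0f} s movement, {ks.n_inversions} inversions, "
            f"mean |omega| "
            + (
                f"{ks.mean_angular_speed_rad_s:.2f} rad/s)"
                if ks.mean_angular_speed_rad_s is not None else "undefined)"
            )
        )
        with pd.option_context("display.width", 200, "display.max_columns", 50):
            body = df[cols].round(3).to_string(index=False)
        return head + "\n" + body

    def layer_comparisons(self) -> list[GroupComparison]:
        """The standard L2-versus-L3 comparison set (see :func:`layer_summary`)."""
        return layer_summary(self.reports)

    def to_json(self, path: str | Path | None = None) -> str:
        """Deterministic JSON export: identical inputs+config+seed give
        byte-identical output."""
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": _pkg_version,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "kinematics_summary": self.kinematics_summary.to_dict(),
            "cells": [r.to_dict() for r in self.reports],
        }
        text = json.dumps(payload, sort_keys=True, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# cohort-level summaries
# ---------------------------------------------------------------------------

def layer_summary(
    reports: Sequence[CellReport],
    layer_a: str = "L2",
    layer_b: str = "L3",
) -> list[GroupComparison]:
    """The standard two-layer comparison set.

    HD index, theta index, spike half-width and negativity amplitude by
    Mann-Whitney; fraction of HD cells by Fisher's exact test.  Cells with an
    absent statistic are excluded from that comparison only.
    """
    groups = {
        lab: [r for r in reports if r.layer == lab] for lab in (layer_a, layer_b)
    }
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError(
            f"need cells in both layers {layer_a!r} and {layer_b!r}"
        )
    names = (layer_a, layer_b)
    out: list[GroupComparison] = []

    def _collect(get, name):
        a = [get(r) for r in groups[layer_a]]
        b = [get(r) for r in groups[layer_b]]
        a = [v for v in a if v is not None]
        b = [v for v in b if v is not None]
        if a and b:
            out.append(mann_whitney(a, b, name, names))

    _collect(lambda r: r.hd.hd_index if r.hd else None, "hd_index")
    counts = []
    for lab in names:
        flagged = [r.hd.is_hd for r in groups[lab] if r.hd is not None]
        counts.append([int(sum(flagged)), int(len(flagged) - sum(flagged))])
    out.append(fisher_exact(np.asarray(counts), "fraction_hd_cells", names))
    _collect(lambda r: r.theta.theta_index if r.theta else None, "theta_index")
    _collect(
        lambda r: r.features.half_width_ms if r.features else None,
        "half_width_ms",
    )
    _collect(
        lambda r: r.features.negativity_amp if r.features else None,
        "negativity_amp",
    )
    return out


def composition_table(counts: Mapping[str, int], total: int) -> pd.DataFrame:
    """Marker-composition report table: counts and percentages of a total.

    E.g. calbindin-positive versus -negative cell counts within a layer; the
    ``pct`` column is ``100 * n / total``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rows = [
        {"marker": k, "n": int(v), "total": int(total), "pct": 100.0 * v / total}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)
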
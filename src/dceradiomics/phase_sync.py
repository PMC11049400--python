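"""Bolus-curve phase synchronization.

A reference-vessel ROI is reduced to its median-intensity enhancement
curve, and seven contrast-agent phases (TP1-TP7) are selected from it:

* TP1 — the second acquired scan (pre-bolus reference);
* TP2 — the earliest scan whose median intensity is at least
  ``(1 + rise_fraction)`` times the mean of the first two scans (wash-in
  onset; first-crossing semantics);
* TP4 — the scan with peak median intensity (ties break to the earliest);
* TP3 — the scan whose acquisition time is nearest the midpoint of the
  TP2 and TP4 times (ties break to the earlier scan);
* TP6 — the last scan at least ``(1 + rise_fraction)`` times the mean of
  the final two scans (washout end, mirroring TP2);
* TP5 — the scan nearest the time midpoint of TP4 and TP6;
* TP7 — the second-to-last acquired scan.

Midpoints are taken on the acquisition-time axis, not the scan index,
because the inter-scan interval changes mid-series.  The threshold is
relative, so phase selection is invariant under pure positive scaling of
the curve; adding an offset can move TP2/TP6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DynamicSeries, ImageVolume, RoiMask

PHASE_LABELS = tuple(f"TP{i}" for i in range(1, 8))


class PhaseDetectionError(ValueError):
    """The bolus or washout event required by a phase rule was not found."""


@dataclass
class PhaseSyncConfig:
    rise_fraction: float = 0.15
    midpoint_axis: str = "time"   # "time" (default) or "index"
    tp2_rule: str = "first_crossing"  # or "nearest_to_threshold"

    def __post_init__(self) -> None:
        if not 0 < self.rise_fraction < 1:
            raise ValueError("rise_fraction must be in (0, 1)")
        if self.midpoint_axis not in ("time", "index"):
            raise ValueError("midpoint_axis must be 'time' or 'index'")
        if self.tp2_rule not in ("first_crossing", "nearest_to_threshold"):
            raise ValueError("unknown tp2_rule")


@dataclass
class EnhancementCurve:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) < 7:
            raise ValueError("curve must have at least 7 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "median_intensity": self.values})


@dataclass
class PhaseAssignment:
    tp: tuple[int, int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.tp) != 7:
            raise ValueError("exactly seven phase indices required")
        self.tp = tuple(int(i) for i in self.tp)
        if any(b < a for a, b in zip(self.tp, self.tp[1:])):
            raise PhaseDetectionError(f"phase ordering violated: {self.tp}")

    def to_frame(self, times=None) -> pd.DataFrame:
        df = pd.DataFrame({"phase": PHASE_LABELS, "scan_index": list(self.tp)})
        if times is not None:
            df["time_s"] = np.asarray(times, dtype=float)[list(self.tp)]
        return df


def median_enhancement_curve(series: DynamicSeries, vessel: RoiMask) -> EnhancementCurve:
    """Median vessel-ROI intensity per scan."""
    ref = series.volumes[0]
    if not vessel.geometry_equal(ref):
        raise ValueError("vessel mask geometry does not match the series")
    if not vessel.voxels.any():
        raise ValueError("empty ROI: vessel mask has no foreground voxels")
    values = np.array([float(np.median(v.voxels[vessel.voxels])) for v in series.volumes])
    return EnhancementCurve(times=series.acquisition_times.copy(), values=values)


def _nearest(axis_values: np.ndarray, lo: int, hi: int, target: float) -> int:
    """Index in [lo, hi] whose axis value is nearest target; ties -> earlier."""
    idx = np.arange(lo, hi + 1)
    dist = np.abs(axis_values[idx] - target)
    return int(idx[int(np.argmin(dist))])  # argmin takes the first minimum


def define_phases(curve: EnhancementCurve, cfg: PhaseSyncConfig | None = None) -> PhaseAssignment:
    """Select the seven phase scan indices from an enhancement curve."""
    cfg = cfg or PhaseSyncConfig()
    v = curve.values
    t = curve.times if cfg.midpoint_axis == "time" else np.arange(len(v), dtype=float)
    n = len(v)

    tp1 = 1
    tp4 = int(np.argmax(v))  # earliest scan at the peak value

    rise = 1.0 + cfg.rise_fraction
    thr_head = rise * float(np.mean(v[:2]))
    above_head = np.flatnonzero(v >= thr_head)
    if above_head.size == 0:
        raise PhaseDetectionError("no bolus detected: curve never rises 15% above baseline")
    if cfg.tp2_rule == "first_crossing":
        tp2 = int(above_head[0])
    else:  # nearest-to-threshold reading of the same sentence
        tp2 = int(np.argmin(np.abs(v - thr_head)))

    thr_tail = rise * float(np.mean(v[-2:]))
    above_tail = np.flatnonzero(v >= thr_tail)
    if above_tail.size == 0:
        raise PhaseDetectionError("no washout detected: tail threshold never reached")
    tp6 = int(above_tail[-1])

    tp3 = _nearest(t, min(tp2, tp4), max(tp2, tp4), 0.5 * (t[tp2] + t[tp4]))
    tp5 = _nearest(t, min(tp4, tp6), max(tp4, tp6), 0.5 * (t[tp4] + t[tp6]))
    tp7 = n - 2

    return PhaseAssignment(tp=(tp1, tp2, tp3, tp4, tp5, tp6, tp7))


def phase_volumes(series: DynamicSeries, assignment: PhaseAssignment
                  ) -> list[tuple[ImageVolume, str]]:
    """The seven phase volumes with their TP labels; duplicate indices are
    allowed (short series may assign one scan to several phases)."""
    n = len(series)
    for idx in assignment.tp:
        if not 0 <= idx < n:
            raise IndexError(f"phase index {idx} out of range for a {n}-scan series")
    return [(series.volumes[idx], label) for idx, label in zip(assignment.tp, PHASE_LABELS)]
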
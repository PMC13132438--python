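"""Per-beat morphological feature extraction.

The 17-entry feature registry is this module's definition; each entry has a
fixed measurement window relative to the R-peak.  The windows partition the
-200..+340 ms beat segment:

    P wave      -200 .. -60 ms   (signed extremum)
    QRS          -60 .. +60 ms   (R = max; Q/S = minima before/after R)
    ST segment   +60 .. +100 ms  (mean level, linear slope)
    T wave      +120 .. +340 ms  (signed extremum)

Wave durations use 10%-of-peak crossings; features that are undefined on a
flat segment are recorded as NaN (missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import BeatSet

__all__ = ["FEATURE_REGISTRY", "FeatureWindows", "beat_features"]

FEATURE_REGISTRY: tuple[str, ...] = (
    "rr_prev", "rr_next", "inst_hr",
    "p_amp", "p_dur", "pr_interval",
    "q_amp", "r_amp", "s_amp", "qrs_dur",
    "st_level", "st_slope",
    "t_amp", "t_dur", "qt_interval", "t_peak_time",
    "beat_rms",
)


@dataclass(frozen=True)
class FeatureWindows:
    """Measurement windows (ms relative to R)."""

    p: tuple[float, float] = (-200.0, -60.0)
    qrs: tuple[float, float] = (-60.0, 60.0)
    st: tuple[float, float] = (60.0, 100.0)
    t: tuple[float, float] = (120.0, 340.0)
    duration_frac: float = 0.1      # crossing level as a fraction of peak


def _win_slice(t_ms: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.flatnonzero((t_ms >= lo) & (t_ms <= hi))


def _signed_extremum(seg: np.ndarray, idx: np.ndarray) -> tuple[float, int]:
    sub = seg[idx]
    k = int(np.argmax(np.abs(sub)))
    return float(sub[k]), int(idx[k])


def _crossings(seg: np.ndarray, peak_idx: int, level: float, lo: int, hi: int) -> tuple[int, int]:
    """Walk out from a peak until |seg| drops below ``level`` (bounded)."""
    left = peak_idx
    while left > lo and abs(seg[left - 1]) >= level:
        left -= 1
    right = peak_idx
    while right < hi - 1 and abs(seg[right + 1]) >= level:
        right += 1
    return left, right


def beat_features(
    beats: BeatSet,
    windows: FeatureWindows = FeatureWindows(),
) -> pd.DataFrame:
    """Feature vectors for every beat, columns in FEATURE_REGISTRY order."""
    t_ms = beats.time_rel_ms
    fs = beats.fs
    rows = []
    p_idx = _win_slice(t_ms, *windows.p)
    qrs_idx = _win_slice(t_ms, *windows.qrs)
    st_idx = _win_slice(t_ms, *windows.st)
    t_idx = _win_slice(t_ms, *windows.t)
    frac = windows.duration_frac

    for b in range(len(beats)):
        seg = beats.segments[b]
        feat: dict[str, float] = {
            "rr_prev": float(beats.rr_prev_ms[b]),
            "rr_next": float(beats.rr_next_ms[b]),
        }
        feat["inst_hr"] = 60000.0 / ((feat["rr_prev"] + feat["rr_next"]) / 2.0)

        # P wave
        p_amp, p_peak = _signed_extremum(seg, p_idx)
        feat["p_amp"] = p_amp
        if abs(p_amp) > 0:
            lo, hi = _crossings(seg, p_peak, frac * abs(p_amp), p_idx[0], p_idx[-1] + 1)
            feat["p_dur"] = (hi - lo) / fs * 1000.0
            feat["pr_interval"] = -t_ms[lo]          # P onset to R
        else:
            feat["p_dur"] = np.nan
            feat["pr_interval"] = np.nan

        # QRS
        r_i = beats.r_index
        feat["r_amp"] = float(seg[r_i])
        before = qrs_idx[qrs_idx < r_i]
        after = qrs_idx[qrs_idx > r_i]
        feat["q_amp"] = float(seg[before].min()) if before.size else np.nan
        feat["s_amp"] = float(seg[after].min()) if after.size else np.nan
        if abs(feat["r_amp"]) > 0:
            lo, hi = _crossings(seg, r_i, frac * abs(feat["r_amp"]), qrs_idx[0], qrs_idx[-1] + 1)
            feat["qrs_dur"] = (hi - lo) / fs * 1000.0
            qrs_onset = lo
        else:
            feat["qrs_dur"] = np.nan
            qrs_onset = None

        # ST segment
        st_seg = seg[st_idx]
        feat["st_level"] = float(st_seg.mean())
        slope = np.polyfit(t_ms[st_idx] / 1000.0, st_seg, 1)[0] if st_idx.size > 1 else np.nan
        feat["st_slope"] = float(slope)              # mV/s

        # T wave
        t_amp, t_peak = _signed_extremum(seg, t_idx)
        feat["t_amp"] = t_amp
        if abs(t_amp) > 0:
            lo, hi = _crossings(seg, t_peak, frac * abs(t_amp), t_idx[0], t_idx[-1] + 1)
            feat["t_dur"] = (hi - lo) / fs * 1000.0
            feat["t_peak_time"] = float(t_ms[t_peak])
            feat["qt_interval"] = (
                float(t_ms[hi] - t_ms[qrs_onset]) if qrs_onset is not None else np.nan
            )
        else:
            feat["t_dur"] = np.nan
            feat["t_peak_time"] = np.nan
            feat["qt_interval"] = np.nan

        feat["beat_rms"] = float(np.sqrt(np.mean(seg**2)))
        rows.append(feat)

    df = pd.DataFrame(rows, columns=list(FEATURE_REGISTRY))
    df.insert(0, "patient_id", beats.patient_id)
    df.insert(1, "lead", beats.lead)
    return df
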
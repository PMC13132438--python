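"""Pixel polyline -> calibrated, resampled, band-pass-filtered signal."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = ["CalibratedSignal", "TooShortSignalError", "to_signal", "bandpass", "estimate_baseline"]

TARGET_FS = 500.0
MIN_DURATION_S = 2.0


class TooShortSignalError(ValueError):
    """Digitised trace shorter than the minimum usable duration."""


@dataclass
class CalibratedSignal:
    """Uniformly sampled, unit-calibrated single-lead trace."""

    lead: str
    samples: np.ndarray          # mV
    fs: float = TARGET_FS        # Hz
    baseline_mv: float = 0.0
    source_panel: tuple[int, int, int, int] | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float = 0.5,
    high: float = 40.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def to_signal(
    polyline_rows: np.ndarray,
    calibration,
    baseline_row: float,
    lead: str = "II",
    fs: float = TARGET_FS,
    band: tuple[float, float] = (0.5, 40.0),
    filter_order: int = 5,
    source_panel: tuple[int, int, int, int] | None = None,
    apply_filter: bool = True,
    px_center_offset: float = 0.5,
) -> CalibratedSignal:
    """Convert per-column ordinates to a 500 Hz, band-passed mV signal.

    Columns map to time via ``ms_per_px``; rows to mV via
    ``(baseline_row - row) * mv_per_px``.  Rasterisation truncates
    coordinates, so integer pixel index j represents physical coordinate
    j + ``px_center_offset`` in both axes (pixel-centre convention).  The
    trace is linearly resampled to ``fs`` and band-pass filtered (zero
    phase, order ``filter_order``).
    """
    rows = np.asarray(polyline_rows, dtype=float) + px_center_offset
    if rows.size == 0:
        raise ValueError("empty polyline")
    t_ms = (np.arange(rows.size) + px_center_offset) * calibration.ms_per_px
    duration_s = t_ms[-1] / 1000.0
    if duration_s < MIN_DURATION_S:
        raise TooShortSignalError(
            f"digitised trace lasts {duration_s:.2f} s (< {MIN_DURATION_S} s)"
        )
    mv = (baseline_row - rows) * calibration.mv_per_px
    n_out = int(round(duration_s * fs))
    t_uniform = np.arange(n_out) / fs * 1000.0
    resampled = np.interp(t_uniform, t_ms, mv)
    if apply_filter:
        resampled = bandpass(resampled, fs, band[0], band[1], filter_order)
    return CalibratedSignal(
        lead=lead, samples=resampled, fs=fs, source_panel=source_panel
    )


def estimate_baseline(
    signal: CalibratedSignal | np.ndarray,
    r_peaks_ms: np.ndarray,
    fs: float | None = None,
    tp_start_ms: float = 340.0,
    tp_end_before_next_ms: float = 200.0,
) -> np.ndarray:
    """Per-beat isoelectric baseline as the TP-segment mean.

    The TP window runs from R + ``tp_start_ms`` to next-R -
    ``tp_end_before_next_ms``; when that window is empty (tachycardia) the
    global median of the signal is used as a fallback.  Returns one baseline
    value per beat (the last beat, lacking a next R, gets the fallback).
    """
    if isinstance(signal, CalibratedSignal):
        x, fs = signal.samples, signal.fs
    else:
        x = np.asarray(signal, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    r = np.asarray(r_peaks_ms, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 R-peaks to locate TP segments")
    fallback = float(np.median(x))
    out = np.full(r.size, fallback)
    for i in range(r.size - 1):
        lo_ms = r[i] + tp_start_ms
        hi_ms = r[i + 1] - tp_end_before_next_ms
        lo = int(np.ceil(lo_ms / 1000.0 * fs))
        hi = int(np.floor(hi_ms / 1000.0 * fs))
        if hi > lo and lo >= 0 and hi <= len(x):
            out[i] = float(np.mean(x[lo:hi]))
    return out
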
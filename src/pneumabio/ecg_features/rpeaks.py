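"""R-peak detection: Pan-Tompkins stages with adaptive dual thresholds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = ["RPeakResult", "detect_r_peaks"]


@dataclass
class RPeakResult:
    times_ms: np.ndarray
    status: str = "ok"       # "ok" | "no_peaks"

    def __len__(self) -> int:
        return len(self.times_ms)


def _pan_tompkins_candidates(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """QRS band-pass, derivative, squaring, 150 ms moving-window integration."""
    sos = butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    cand, _ = find_peaks(mwi, distance=int(round(0.2 * fs)))
    return bp, mwi, cand


def detect_r_peaks(
    signal,
    fs: float | None = None,
    refine_ms: float = 25.0,
) -> RPeakResult:
    """Detect R peaks on a 500 Hz calibrated signal.

    Stages: 5-15 Hz band-pass, derivative, squaring, 150 ms moving-window
    integration, then adaptive signal/noise thresholds with a half-threshold
    search-back over long RR gaps.  Detections are refined to the local
    maximum of the band-passed signal within ``refine_ms`` of the candidate.
    """
    if hasattr(signal, "samples"):
        x, fs = np.asarray(signal.samples, dtype=float), signal.fs
    else:
        x = np.asarray(signal, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if len(x) < int(2 * fs):
        raise ValueError("signal must last at least 2 s")
    if np.allclose(x, 0.0):
        return RPeakResult(times_ms=np.empty(0), status="no_peaks")

    bp, mwi, cand = _pan_tompkins_candidates(x, fs)
    if cand.size == 0:
        return RPeakResult(times_ms=np.empty(0), status="no_peaks")
    slope = np.abs(np.gradient(bp))
    slope_win = int(round(0.075 * fs))

    def max_slope(idx: int) -> float:
        lo = max(idx - slope_win, 0)
        return float(slope[lo : idx + slope_win + 1].max())

    # adaptive dual thresholds (Pan-Tompkins running estimates)
    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    accepted: list[int] = []
    recent_rr: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        peak = mwi[c]
        if peak > threshold():
            # T-wave discrimination: a candidate within 360 ms of the last
            # accepted QRS whose maximal slope is under half of that QRS's
            # slope is a repolarisation wave, not a beat
            if accepted and (c - accepted[-1]) / fs * 1000.0 < 360.0:
                if max_slope(c) < 0.5 * max_slope(accepted[-1]):
                    npki = 0.125 * peak + 0.875 * npki
                    continue
            if accepted:
                recent_rr.append((c - accepted[-1]) / fs * 1000.0)
                recent_rr[:] = recent_rr[-8:]
            accepted.append(c)
            spki = 0.125 * peak + 0.875 * spki
        else:
            # search-back: accept at half threshold if the RR gap is long
            if accepted and recent_rr:
                gap_ms = (c - accepted[-1]) / fs * 1000.0
                if gap_ms > 1.66 * float(np.mean(recent_rr)) and peak > 0.5 * threshold():
                    recent_rr.append(gap_ms)
                    recent_rr[:] = recent_rr[-8:]
                    accepted.append(c)
                    spki = 0.25 * peak + 0.75 * spki
                    continue
            npki = 0.125 * peak + 0.875 * npki

    if not accepted:
        return RPeakResult(times_ms=np.empty(0), status="no_peaks")

    # refine to local maximum of the band-passed signal
    half = int(round(refine_ms / 1000.0 * fs))
    refined = []
    for c in accepted:
        lo = max(c - half, 0)
        hi = min(c + half + 1, len(bp))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined_arr = np.unique(np.asarray(refined))
    return RPeakResult(times_ms=refined_arr / fs * 1000.0, status="ok")
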
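"""Grid calibration: estimate pixels-per-mm from grid periodicity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = ["GridCalibration", "CalibrationError", "calibrate_grid"]


class CalibrationError(RuntimeError):
    """No stable grid periodicity could be found."""


@dataclass(frozen=True)
class GridCalibration:
    px_per_mm_x: float
    px_per_mm_y: float
    paper_speed: float = 25.0   # mm/s
    amp_scale: float = 10.0     # mm/mV

    def __post_init__(self) -> None:
        if self.px_per_mm_x <= 0 or self.px_per_mm_y <= 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def ms_per_px(self) -> float:
        return 1000.0 / (self.paper_speed * self.px_per_mm_x)

    @property
    def mv_per_px(self) -> float:
        return 1.0 / (self.amp_scale * self.px_per_mm_y)


def _dominant_period(profile: np.ndarray, max_lag: int) -> float:
    """Fundamental period of a 1-D intensity profile via autocorrelation.

    Takes the smallest-lag autocorrelation peak whose height is comparable
    to the global maximum (>= 50%), then refines it by parabolic
    interpolation.  Returns NaN when no usable peak exists.
    """
    x = profile - profile.mean()
    if np.allclose(x, 0.0):
        return float("nan")
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    ac = ac / ac[0]
    ac = ac[: max_lag + 1]
    peaks, props = find_peaks(ac[1:], height=0.05)
    if len(peaks) == 0:
        return float("nan")
    heights = props["peak_heights"]
    best = heights.max()
    candidates = peaks[heights >= 0.5 * best] + 1  # +1: offset from ac[1:]
    lag = int(candidates.min())
    if lag < 2 or lag + 1 >= len(ac):
        return float("nan")
    # refine using the highest-order harmonic peak that fits: its lag is
    # k * period, so dividing by k shrinks the relative pixel error k-fold
    k = max(int((len(ac) - 2) // lag), 1)
    approx = k * lag
    lo = max(approx - lag // 2, 1)
    hi = min(approx + lag // 2 + 1, len(ac) - 1)
    lag_k = lo + int(np.argmax(ac[lo:hi]))
    y0, y1, y2 = ac[lag_k - 1], ac[lag_k], ac[lag_k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if abs(denom) < 1e-12 else 0.5 * (y0 - y2) / denom
    return (lag_k + float(np.clip(shift, -0.5, 0.5))) / k


def _has_big_box_harmonic(profile: np.ndarray, period: float) -> bool:
    """Check that the 5x (big-box) periodicity is present."""
    x = profile - profile.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    ac = ac / ac[0]
    lag5 = int(round(5 * period))
    if lag5 + 1 >= len(ac):
        return False
    window = ac[max(lag5 - 2, 1) : lag5 + 3]
    return bool(window.max() > 0.05)


def calibrate_grid(
    image: np.ndarray,
    paper_speed: float = 25.0,
    amp_scale: float = 10.0,
) -> GridCalibration:
    """Estimate px/mm from the dominant periodicity of row/column projections.

    The small-box (1 mm) spacing is the fundamental period; a 5x harmonic
    (big box) must also be present, otherwise calibration fails.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    col_profile = img.mean(axis=0)   # vertical grid lines -> x spacing
    row_profile = img.mean(axis=1)   # horizontal grid lines -> y spacing

    px_x = _dominant_period(col_profile, max(len(col_profile) // 2, 10))
    px_y = _dominant_period(row_profile, max(len(row_profile) // 2, 10))
    if not np.isfinite(px_x) or not np.isfinite(px_y):
        raise CalibrationError("no stable grid periodicity found")
    if not (_has_big_box_harmonic(col_profile, px_x) and _has_big_box_harmonic(row_profile, px_y)):
        raise CalibrationError("5x big-box harmonic missing; grid not validated")
    return GridCalibration(
        px_per_mm_x=px_x, px_per_mm_y=px_y,
        paper_speed=paper_speed, amp_scale=amp_scale,
    )
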
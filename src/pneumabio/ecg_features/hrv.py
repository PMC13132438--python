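"""Ultra-short HRV metrics from NN intervals.

Definitions (ms unless noted):

    mean_nn = mean(NN)
    sdnn    = sample SD of NN (ddof 1)
    rmssd   = sqrt(mean(diff(NN)^2))
    sd1     = rmssd / sqrt(2)                       (Poincare identity)
    sd2     = sqrt(max(0, 2*sdnn_pop^2 - sd1^2)),   sdnn_pop = population SD
    apen    = approximate entropy, m = 2, r = 0.2 * sdnn_pop
    mean_hr = 60000 / mean_nn                       (beats/min)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["HrvMetrics", "InsufficientDataError", "hrv_metrics", "approximate_entropy"]


class InsufficientDataError(ValueError):
    """Fewer than 3 NN intervals in the analysis window."""


@dataclass(frozen=True)
class HrvMetrics:
    mean_nn: float
    sdnn: float
    rmssd: float
    sd1: float
    sd2: float
    apen: float
    mean_hr: float
    n_nn: int


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) of a series; r defaults to 0.2 * population SD.

    Returns 0.0 for constant series (no information).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.2 * float(np.std(x, ddof=0))
    if r <= 0 or n <= m + 1:
        return 0.0

    def phi(mm: int) -> float:
        count = n - mm + 1
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distance between all template pairs
        dist = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
        c = (dist <= r).sum(axis=1) / count
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def hrv_metrics(
    nn_intervals_ms: np.ndarray,
    window_s: float | None = 10.0,
) -> HrvMetrics:
    """HRV metrics over the NN intervals falling inside the first ``window_s``
    seconds (cumulative-time truncation); pass None to use all intervals.
    """
    nn = np.asarray(nn_intervals_ms, dtype=float)
    if window_s is not None and nn.size:
        cum = np.cumsum(nn)
        nn = nn[cum <= window_s * 1000.0 + 1e-9]
    if nn.size < 3:
        raise InsufficientDataError(
            f"need >= 3 NN intervals in the window, got {nn.size}"
        )
    mean_nn = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    sdnn_pop = float(np.std(nn, ddof=0))
    diffs = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    sd1 = rmssd / math.sqrt(2.0)
    sd2 = math.sqrt(max(0.0, 2.0 * sdnn_pop**2 - sd1**2))
    apen = approximate_entropy(nn, m=2, r=0.2 * sdnn_pop)
    return HrvMetrics(
        mean_nn=mean_nn,
        sdnn=sdnn,
        rmssd=rmssd,
        sd1=sd1,
        sd2=sd2,
        apen=apen,
        mean_hr=60000.0 / mean_nn,
        n_nn=int(nn.size),
    )
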
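"""RR filtering and beat segmentation around detected R-peaks.

A beat is retained only when both its preceding and following RR intervals
lie inside the physiological 300-2000 ms range; the first and last detected
beats lack one RR and are always dropped.  Retained beats are cut to the
-200..+340 ms analysis window, baseline-subtracted, with the R sample at
index ``round(0.2 * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RR_MIN_MS", "RR_MAX_MS", "SEG_PRE_MS", "SEG_POST_MS",
           "RetainedBeats", "BeatSet", "filter_rr", "segment_beats"]

RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0
SEG_PRE_MS = 200.0
SEG_POST_MS = 340.0


@dataclass
class RetainedBeats:
    r_times_ms: np.ndarray
    rr_prev_ms: np.ndarray
    rr_next_ms: np.ndarray
    status: str = "ok"        # "ok" | "empty"

    def __len__(self) -> int:
        return len(self.r_times_ms)


@dataclass
class BeatSet:
    """R-aligned beat segments with RR context."""

    patient_id: str
    lead: str
    fs: float
    r_times_ms: np.ndarray
    rr_prev_ms: np.ndarray
    rr_next_ms: np.ndarray
    segments: np.ndarray       # (n_beats, seg_len) mV, baseline-subtracted
    r_index: int               # sample index of R within each segment

    def __len__(self) -> int:
        return len(self.r_times_ms)

    @property
    def time_rel_ms(self) -> np.ndarray:
        n = self.segments.shape[1]
        return (np.arange(n) - self.r_index) / self.fs * 1000.0


def filter_rr(r_peak_times_ms: np.ndarray) -> RetainedBeats:
    """Keep beats whose preceding AND following RR lie in [300, 2000] ms."""
    r = np.asarray(r_peak_times_ms, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 R-peaks to filter RR intervals")
    rr = np.diff(r)
    prev = rr[:-1]
    nxt = rr[1:]
    ok = (prev >= RR_MIN_MS) & (prev <= RR_MAX_MS) & (nxt >= RR_MIN_MS) & (nxt <= RR_MAX_MS)
    times = r[1:-1][ok]
    status = "ok" if times.size else "empty"
    return RetainedBeats(
        r_times_ms=times, rr_prev_ms=prev[ok], rr_next_ms=nxt[ok], status=status
    )


def segment_beats(
    signal,
    retained: RetainedBeats,
    baseline: np.ndarray | float = 0.0,
    patient_id: str = "",
    lead: str = "II",
    fs: float | None = None,
) -> BeatSet:
    """Extract baseline-subtracted -200..+340 ms windows around each R.

    Beats whose window would leave the record are dropped (together with
    their baseline entry when per-beat baselines are supplied).
    """
    if hasattr(signal, "samples"):
        x, fs = np.asarray(signal.samples, dtype=float), signal.fs
    else:
        x = np.asarray(signal, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if len(retained) == 0:
        raise ValueError("no retained beats to segment")

    pre = int(round(SEG_PRE_MS / 1000.0 * fs))
    post = int(round(SEG_POST_MS / 1000.0 * fs))
    seg_len = pre + post + 1

    base = np.broadcast_to(np.atleast_1d(np.asarray(baseline, dtype=float)),
                           (len(retained),)) if np.ndim(baseline) == 0 else np.asarray(baseline, dtype=float)
    if base.shape[0] != len(retained):
        raise ValueError("baseline must be scalar or one value per retained beat")

    segs, keep = [], []
    for i, t in enumerate(retained.r_times_ms):
        c = int(round(t / 1000.0 * fs))
        lo, hi = c - pre, c + post + 1
        if lo < 0 or hi > len(x):
            continue
        segs.append(x[lo:hi] - base[i])
        keep.append(i)
    keep_arr = np.asarray(keep, dtype=int)
    segments = np.vstack(segs) if segs else np.empty((0, seg_len))
    return BeatSet(
        patient_id=patient_id,
        lead=lead,
        fs=fs,
        r_times_ms=retained.r_times_ms[keep_arr],
        rr_prev_ms=retained.rr_prev_ms[keep_arr],
        rr_next_ms=retained.rr_next_ms[keep_arr],
        segments=segments,
        r_index=pre,
    )
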
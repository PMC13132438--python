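"""Synthetic single-lead ECG traces with exact ground truth.

Beats are a sum of Gaussian P/QRS/T bumps on a flat TP baseline, so every
planted amplitude and every R-peak time is known in closed form.  The RR
process is either a deterministic alternating jitter (closed-form RMSSD:
an alternating +/-d series has RMSSD exactly 2d) or a seeded AR(1) jitter,
both hard-clipped to the physiological 300-2000 ms range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EcgSimParams", "SimulatedEcg", "gen_ecg_signal", "gen_rr_sequence"]

RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0

# Bump geometry relative to the R peak (ms).  Chosen so each wave falls
# inside its measurement window: P in -200..-60, QRS in -60..+60,
# ST plateau covering +60..+100, T in +120..+340.
P_CENTER_MS = -130.0
P_SIGMA_MS = 18.0
Q_CENTER_MS = -20.0
Q_SIGMA_MS = 5.0
S_CENTER_MS = 22.0
S_SIGMA_MS = 6.0
R_SIGMA_MS = 7.0
ST_START_MS = 40.0
ST_END_MS = 120.0
ST_EDGE_MS = 3.0
T_CENTER_MS = 215.0
T_SIGMA_MS = 32.0


@dataclass(frozen=True)
class EcgSimParams:
    """Parameters of the synthetic ECG generator."""

    mean_hr: float = 60.0          # beats/min
    rmssd_target: float = 0.0      # ms
    p_amp: float = 0.15            # mV (signed)
    r_amp: float = 1.0             # mV
    s_amp: float = -0.2            # mV (signed)
    t_amp: float = 0.3             # mV (signed)
    st_offset: float = 0.0         # mV
    duration: float = 10.0         # s
    seed: int = 0
    fs: float = 500.0              # Hz
    rr_mode: str = "alternating"   # "alternating" | "ar1"
    noise_mv: float = 0.0          # white-noise SD added to the trace
    q_frac: float = 0.08           # |Q| as a fraction of r_amp

    def __post_init__(self) -> None:
        if not (20.0 < self.mean_hr < 300.0):
            raise ValueError(f"mean_hr must lie in (20, 300), got {self.mean_hr}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rmssd_target < 0:
            raise ValueError("rmssd_target must be non-negative")
        for name in ("p_amp", "r_amp", "s_amp", "t_amp", "st_offset"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.rr_mode not in ("alternating", "ar1"):
            raise ValueError(f"unknown rr_mode {self.rr_mode!r}")


@dataclass
class SimulatedEcg:
    """Ground-truth trace plus exact R-peak times."""

    samples: np.ndarray            # mV, uniformly sampled
    fs: float                      # Hz
    r_peak_times_ms: np.ndarray    # exact planted R times
    rr_ms: np.ndarray              # RR intervals actually used
    params: EcgSimParams = field(repr=False, default=None)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs * 1000.0


def gen_rr_sequence(
    mean_hr: float,
    rmssd_target: float,
    n_beats: int,
    mode: str = "alternating",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate an RR sequence (ms) targeting a given sample RMSSD.

    ``alternating`` plants a deterministic +/- (rmssd/2) jitter whose RMSSD
    equals the target exactly; ``ar1`` draws a seeded AR(1) jitter whose
    expected RMSSD equals the target.  Intervals are clipped to
    [300, 2000] ms; a target that would always leave that range is rejected.
    """
    base = 60000.0 / mean_hr
    delta = rmssd_target / 2.0
    if base - delta < RR_MIN_MS or base + delta > RR_MAX_MS:
        raise ValueError(
            f"rmssd_target={rmssd_target} infeasible at mean_hr={mean_hr}: "
            f"RR {base:.0f}+/-{delta:.0f} ms leaves the 300-2000 ms range"
        )
    if mode == "alternating":
        jitter = delta * (-1.0) ** np.arange(n_beats)
    elif mode == "ar1":
        if rng is None:
            rng = np.random.default_rng()
        phi = 0.3
        # successive-difference variance of AR(1): 2*sig_x^2*(1-phi),
        # sig_x^2 = sig_e^2/(1-phi^2)  =>  sig_e = rmssd*sqrt((1+phi)/2)
        sig_e = rmssd_target * np.sqrt((1.0 + phi) / 2.0)
        eps = rng.normal(0.0, sig_e, size=n_beats)
        jitter = np.empty(n_beats)
        prev = 0.0
        for i in range(n_beats):
            prev = phi * prev + eps[i]
            jitter[i] = prev
    else:
        raise ValueError(f"unknown rr mode {mode!r}")
    return np.clip(base + jitter, RR_MIN_MS, RR_MAX_MS)


def _gauss(t_ms: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


def _st_plateau(t_ms: np.ndarray) -> np.ndarray:
    """Smooth boxcar covering the ST window (logistic edges)."""
    rise = 1.0 / (1.0 + np.exp(-(t_ms - ST_START_MS) / ST_EDGE_MS))
    fall = 1.0 / (1.0 + np.exp((t_ms - ST_END_MS) / ST_EDGE_MS))
    return rise * fall


def beat_waveform(t_rel_ms: np.ndarray, params: EcgSimParams) -> np.ndarray:
    """Single-beat waveform evaluated at times relative to the R peak."""
    w = params.r_amp * _gauss(t_rel_ms, 0.0, R_SIGMA_MS)
    w += params.p_amp * _gauss(t_rel_ms, P_CENTER_MS, P_SIGMA_MS)
    w -= params.q_frac * abs(params.r_amp) * _gauss(t_rel_ms, Q_CENTER_MS, Q_SIGMA_MS)
    w += params.s_amp * _gauss(t_rel_ms, S_CENTER_MS, S_SIGMA_MS)
    w += params.st_offset * _st_plateau(t_rel_ms)
    w += params.t_amp * _gauss(t_rel_ms, T_CENTER_MS, T_SIGMA_MS)
    return w


def gen_ecg_signal(params: EcgSimParams) -> SimulatedEcg:
    """Generate a synthetic trace sampled at ``params.fs`` with exact R times.

    The first R peak sits 400 ms into the record; beats are placed while the
    full analysis window (R + 360 ms) still fits inside the record.
    """
    rng = np.random.default_rng(params.seed)
    duration_ms = params.duration * 1000.0
    # upper bound on the number of RR intervals we might need
    n_max = int(np.ceil(duration_ms / RR_MIN_MS)) + 2
    rr_all = gen_rr_sequence(
        params.mean_hr, params.rmssd_target, n_max, mode=params.rr_mode, rng=rng
    )
    r_times = [400.0]
    for rr in rr_all:
        nxt = r_times[-1] + rr
        if nxt + 360.0 > duration_ms:
            break
        r_times.append(nxt)
    r_times_arr = np.asarray(r_times)
    rr_used = np.diff(r_times_arr)

    n_samples = int(round(params.duration * params.fs))
    t_ms = np.arange(n_samples) / params.fs * 1000.0
    trace = np.zeros(n_samples)
    for r in r_times_arr:
        rel = t_ms - r
        # waveform support is roughly -250..+360 ms around R
        sel = (rel > -300.0) & (rel < 420.0)
        trace[sel] += beat_waveform(rel[sel], params)
    if params.noise_mv > 0:
        trace += rng.normal(0.0, params.noise_mv, size=n_samples)
    return SimulatedEcg(
        samples=trace,
        fs=params.fs,
        r_peak_times_ms=r_times_arr,
        rr_ms=rr_used,
        params=params,
    )
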
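import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pneumabio.ecg_digitise.signal import CalibratedSignal, bandpass
from pneumabio.ecg_features import (
    FEATURE_REGISTRY,
    beat_features,
    beat_template,
    detect_r_peaks,
    filter_rr,
    segment_beats,
)
from pneumabio.ecg_features.beats import RR_MAX_MS, RR_MIN_MS, RetainedBeats, BeatSet
from pneumabio.synthdata import EcgSimParams, gen_ecg_signal
from pneumabio.synthdata.ecg import beat_waveform


def clean_signal(**kwargs):
    params = EcgSimParams(**kwargs)
    sim = gen_ecg_signal(params)
    return sim, CalibratedSignal(lead="II", samples=bandpass(sim.samples, sim.fs), fs=sim.fs)


class TestDetectRPeaks:
    def test_60bpm_count_and_accuracy(self):
        sim, sig = clean_signal(mean_hr=60, rmssd_target=0, duration=10)
        res = detect_r_peaks(sig)
        assert abs(len(res) - 10) <= 1
        err = np.abs(res.times_ms[:, None] - sim.r_peak_times_ms[None, :]).min(axis=1)
        assert err.max() <= 10.0

    def test_zero_signal_empty(self):
        res = detect_r_peaks(np.zeros(5000), fs=500.0)
        assert len(res) == 0
        assert res.status == "no_peaks"

    def test_120bpm_mean_hr(self):
        sim, sig = clean_signal(mean_hr=120, rmssd_target=5, duration=20, seed=2, rr_mode="ar1")
        res = detect_r_peaks(sig)
        rr = np.diff(res.times_ms)
        mean_hr = 60000.0 / rr.mean()
        assert mean_hr == pytest.approx(120.0, abs=2.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(np.zeros(100), fs=500.0)


class TestFilterRr:
    def test_spec_example(self):
        res = filter_rr(np.array([0.0, 250.0, 1050.0, 1850.0, 3950.0]))
        assert len(res) == 1
        assert res.rr_prev_ms[0] == 800.0
        assert res.rr_next_ms[0] == 800.0
        assert res.r_times_ms[0] == 1050.0

    def test_uniform_keeps_interior(self):
        res = filter_rr(np.arange(10) * 1000.0)
        assert len(res) == 8

    def test_all_short_rr_empty(self):
        res = filter_rr(np.arange(10) * 250.0)
        assert len(res) == 0
        assert res.status == "empty"

    def test_needs_three_peaks(self):
        with pytest.raises(ValueError):
            filter_rr(np.array([0.0, 800.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(50, 2500), min_size=2, max_size=30))
    def test_matches_bruteforce(self, rrs):
        peaks = np.concatenate([[0.0], np.cumsum(rrs)])
        res = filter_rr(peaks)
        rr = np.diff(peaks)
        expected = [
            i for i in range(1, len(peaks) - 1)
            if RR_MIN_MS <= rr[i - 1] <= RR_MAX_MS and RR_MIN_MS <= rr[i] <= RR_MAX_MS
        ]
        assert np.allclose(res.r_times_ms, peaks[expected])


class TestSegmentBeats:
    def test_index_arithmetic(self):
        x = np.arange(5000, dtype=float)
        retained = RetainedBeats(
            r_times_ms=np.array([1000.0]),
            rr_prev_ms=np.array([800.0]),
            rr_next_ms=np.array([800.0]),
        )
        bs = segment_beats(x, retained, fs=500.0)
        assert bs.segments.shape == (1, 271)
        assert bs.r_index == 100
        assert bs.segments[0, 0] == 400.0     # sample index 400
        assert bs.segments[0, -1] == 670.0    # sample index 670

    def test_window_underrun_dropped(self):
        retained = RetainedBeats(
            r_times_ms=np.array([100.0, 1000.0]),
            rr_prev_ms=np.array([900.0, 900.0]),
            rr_next_ms=np.array([900.0, 900.0]),
        )
        bs = segment_beats(np.zeros(5000), retained, fs=500.0)
        assert len(bs) == 1

    def test_baseline_subtraction(self):
        retained = RetainedBeats(
            r_times_ms=np.array([1000.0]),
            rr_prev_ms=np.array([800.0]),
            rr_next_ms=np.array([800.0]),
        )
        bs = segment_beats(np.full(2000, 0.1), retained, baseline=0.1, fs=500.0)
        assert np.allclose(bs.segments, 0.0)


def make_beatset(params=None, rr=800.0, fs=500.0):
    """BeatSet with a single analytic beat (exact planted amplitudes)."""
    if params is None:
        params = EcgSimParams()
    pre, post = 100, 170
    t_rel = (np.arange(pre + post + 1) - pre) / fs * 1000.0
    seg = beat_waveform(t_rel, params)
    return BeatSet(
        patient_id="p0", lead="II", fs=fs,
        r_times_ms=np.array([1000.0]),
        rr_prev_ms=np.array([rr]), rr_next_ms=np.array([rr]),
        segments=seg[None, :], r_index=pre,
    )


class TestBeatFeatures:
    def test_registry_has_17_features(self):
        assert len(FEATURE_REGISTRY) == 17

    def test_planted_t_amplitude(self):
        bs = make_beatset(EcgSimParams(t_amp=0.3))
        feats = beat_features(bs)
        assert feats["t_amp"][0] == pytest.approx(0.30, abs=0.02)

    def test_planted_st_offset(self):
        bs = make_beatset(EcgSimParams(st_offset=-0.05, t_amp=0.2))
        feats = beat_features(bs)
        assert feats["st_level"][0] == pytest.approx(-0.05, abs=0.005)

    def test_zero_segment_amplitudes(self):
        bs = make_beatset()
        bs.segments = np.zeros_like(bs.segments)
        feats = beat_features(bs)
        for col in ("p_amp", "q_amp", "r_amp", "s_amp", "t_amp", "st_level", "beat_rms"):
            assert feats[col][0] == 0.0
        for col in ("p_dur", "t_dur", "qrs_dur", "qt_interval"):
            assert np.isnan(feats[col][0])

    def test_rr_features(self):
        bs = make_beatset(rr=750.0)
        feats = beat_features(bs)
        assert feats["rr_prev"][0] == 750.0
        assert feats["rr_next"][0] == 750.0
        assert feats["inst_hr"][0] == pytest.approx(80.0)

    def test_planted_amplitudes_within_10pct_random(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            params = EcgSimParams(
                p_amp=rng.uniform(0.08, 0.25),
                r_amp=rng.uniform(0.5, 1.5),
                s_amp=-rng.uniform(0.1, 0.4),
                t_amp=rng.uniform(0.15, 0.5) * rng.choice([-1.0, 1.0]),
            )
            feats = beat_features(make_beatset(params))
            assert feats["r_amp"][0] == pytest.approx(params.r_amp, rel=0.10)
            assert feats["t_amp"][0] == pytest.approx(params.t_amp, rel=0.10)
            assert feats["p_amp"][0] == pytest.approx(params.p_amp, rel=0.10)


class TestBeatTemplate:
    def test_identical_groups_zero_diff(self):
        beats = np.tile(np.sin(np.linspace(0, 3, 271)), (5, 1))
        cmp = beat_template({"a": beats, "b": beats})
        assert np.allclose(cmp.abs_diff, 0.0)

    def test_planted_difference(self):
        base = np.zeros((4, 271))
        shifted = base.copy()
        shifted[:, 200] += 0.1
        cmp = beat_template({"a": shifted, "b": base})
        assert cmp.abs_diff[200] == pytest.approx(0.1, abs=0.01)
        assert cmp.diff[200] == pytest.approx(0.1, abs=0.01)

    def test_single_beat_template_is_the_beat(self):
        beat = np.sin(np.linspace(0, 3, 271))
        cmp = beat_template({"a": beat[None, :], "b": beat[None, :]})
        assert np.allclose(cmp.templates["a"].mean, beat)
        assert np.allclose(cmp.templates["a"].sd, 0.0)

    def test_identical_beats_sd_zero(self):
        beats = np.tile(np.sin(np.linspace(0, 3, 271)), (7, 1))
        cmp = beat_template({"a": beats, "b": beats[:2]})
        assert np.allclose(cmp.templates["a"].mean, beats[0])
        assert np.allclose(cmp.templates["a"].sd, 0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            beat_template({"a": np.empty((0, 271)), "b": np.zeros((1, 271))})
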
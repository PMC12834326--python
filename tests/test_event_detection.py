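"""Detectors: spreading depolarization thresholds, seizure counting rules,
R-peak/RR extraction, and vigilance-state scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcemu.core import TimeSeries
from dcemu.event_detection import (
    HypnogramEpoch, SdDetectorParams, classify_sov, consolidate_seizures,
    detect_r_peaks, detect_sd, detect_seizure_candidates, rr_intervals,
    sd_propagation_order,
)
from dcemu.signal_conditioning import lowpass

FS = 1000.0


def volts(values, fs=FS, label="HPL"):
    return TimeSeries(np.asarray(values, float), fs_hz=fs, units="V", label=label)


def sd_excursion(depth_v=0.035, ramp_s=10.0, plateau_s=30.0, recovery_s=20.0,
                 lead_s=60.0, tail_s=60.0, fs=FS):
    """Baseline, linear fall, plateau, linear recovery, baseline."""
    segs = [np.zeros(int(lead_s * fs)),
            np.linspace(0, -depth_v, int(ramp_s * fs), endpoint=False),
            np.full(int(plateau_s * fs), -depth_v),
            np.linspace(-depth_v, 0, int(recovery_s * fs), endpoint=False),
            np.zeros(int(tail_s * fs))]
    return np.concatenate(segs)


def brute_force_sd(x_filtered, fs, params):
    """Independent per-sample scan of the onset/offset rules."""
    k = int(round(params.lookback_s * fs))
    events = []
    i = k
    n = len(x_filtered)
    while i < n:
        if x_filtered[i] - x_filtered[i - k] < -(params.onset_drop_v
                                                 - params.crossing_tol_v):
            onset = i
            thr = x_filtered[onset] + params.offset_margin_v
            j = onset + 1
            while j < n and x_filtered[j] < thr - params.crossing_tol_v:
                j += 1
            off = j if j < n else n - 1
            events.append((onset, off))
            i = off + 1
        else:
            i += 1
    return events


class TestDetectSd:
    def test_flat_trace_yields_nothing(self):
        assert detect_sd(volts(np.full(200000, 0.001))) == []

    def test_single_excursion_matches_bruteforce_scan(self):
        ts = volts(sd_excursion())
        params = SdDetectorParams()
        events = detect_sd(ts, params)
        oracle = brute_force_sd(lowpass(ts, params.lowpass_cutoff_hz).values,
                                FS, params)
        assert len(events) == len(oracle) == 1
        onset_idx, off_idx = oracle[0]
        assert events[0].onset_s == pytest.approx(onset_idx / FS)
        assert events[0].offset_s == pytest.approx(off_idx / FS)
        # ramp slope 3.5 mV/s -> the 3 s look-back drop first exceeds
        # 7.5 mV ~2.14 s into the ramp
        assert events[0].onset_s == pytest.approx(60.0 + 7.5 / 3.5, abs=0.5)
        # offset during the recovery, at onset potential + 2 mV
        assert 100.0 < events[0].offset_s < 120.0
        assert not events[0].truncated
        assert events[0].amplitude_v > 0
        assert events[0].duration_s == pytest.approx(
            events[0].offset_s - events[0].onset_s)

    def test_two_excursions_two_events(self):
        one = sd_excursion(lead_s=60, tail_s=0)
        gap = np.zeros(int(120 * FS))
        two = sd_excursion(lead_s=0, tail_s=60)
        events = detect_sd(volts(np.concatenate([one, gap, two])))
        assert len(events) == 2
        for ev in events:
            # duration on the 30-60 s scale of the planted excursions
            assert 20.0 < ev.duration_s < 90.0

    def test_unrecovered_event_flagged_truncated(self):
        x = np.concatenate([np.zeros(int(60 * FS)),
                            np.linspace(0, -0.035, int(10 * FS)),
                            np.full(int(60 * FS), -0.035)])
        events = detect_sd(volts(x))
        assert len(events) == 1 and events[0].truncated

    def test_sampling_rate_too_low_rejected(self):
        with pytest.raises(ValueError, match="look-back"):
            detect_sd(volts(np.zeros(100), fs=0.1))

    def test_five_mv_shift_below_threshold(self):
        # seizure-associated DC shifts (~5 mV) never trigger the SD detector
        assert detect_sd(volts(sd_excursion(depth_v=0.005))) == []


class TestSeizureCandidates:
    def noisy_background(self, rng, n):
        from dcemu.signal_conditioning import bandpass
        return bandpass(volts(rng.standard_normal(n)), 0.5, 45.0).values * 50e-6

    def test_planted_12hz_burst_found_with_90pct_overlap(self, rng):
        n = int(600 * FS)
        x = self.noisy_background(rng, n)
        t = np.arange(n) / FS
        on, off = 300.0, 330.0
        burst = (t >= on) & (t < off)
        x[burst] += 10 * np.sqrt(np.mean(x ** 2)) * np.sin(
            2 * np.pi * 12.0 * t[burst])
        cands = detect_seizure_candidates({"HPL": volts(x)})
        assert len(cands) == 1
        c_on, c_off, labels = cands[0]
        overlap = min(off, c_off) - max(on, c_on)
        assert overlap >= 0.9 * (off - on)
        assert labels == frozenset({"HPL"})

    def test_burst_outside_band_ignored(self, rng):
        n = int(600 * FS)
        x = self.noisy_background(rng, n)
        t = np.arange(n) / FS
        burst = (t >= 300) & (t < 330)
        x[burst] += 10 * np.sqrt(np.mean(x ** 2)) * np.sin(
            2 * np.pi * 40.0 * t[burst])
        assert detect_seizure_candidates({"HPL": volts(x)}) == []

    def test_stationary_noise_quiet(self, rng):
        x = self.noisy_background(rng, int(900 * FS))
        assert detect_seizure_candidates({"HPL": volts(x)}) == []

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="band"):
            detect_seizure_candidates({"A": volts(np.zeros(100), fs=30.0)})


class TestConsolidateSeizures:
    def test_empty(self):
        assert consolidate_seizures([]) == []

    def test_merge_then_filter_example(self):
        # gaps 120 s and 1760 s -> (0, 240) and (2000, 2100)
        events = consolidate_seizures([(0, 60), (180, 240), (2000, 2100)])
        assert [(e.onset_s, e.offset_s) for e in events] == [(0, 240),
                                                             (2000, 2100)]

    def test_short_candidate_discarded(self):
        assert consolidate_seizures([(100, 109)]) == []
        assert consolidate_seizures([(100, 110)]) == []       # exactly 10 s
        assert len(consolidate_seizures([(100, 110.5)])) == 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            consolidate_seizures([(100, 160), (0, 60)])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(0, 10000), st.floats(0.5, 300)),
                    max_size=20))
    def test_output_invariants(self, raw):
        cands = sorted((on, on + dur) for on, dur in raw)
        events = consolidate_seizures(cands)
        for e in events:
            assert e.duration_s > 10.0
        for a, b in zip(events, events[1:]):
            assert b.onset_s - a.offset_s >= 600.0


class TestRPeaks:
    def test_zero_signal_no_peaks(self):
        assert len(detect_r_peaks(volts(np.zeros(50000), label="ECG"))) == 0

    def test_synthetic_train_recovered(self):
        # 6 Hz R rate (360 bpm), 120 s -> 720 +- 2 peaks within 5 ms
        n = int(120 * FS)
        x = np.zeros(n)
        planted = np.arange(0.3, 119.9, 1 / 6.0)
        idx = np.round(planted * FS).astype(int)
        half = 20
        kt = np.arange(-half, half + 1) / FS
        kernel = 5e-4 * np.exp(-(kt / 0.003) ** 2)
        for i in idx:
            x[i - half: i + half + 1] += kernel
        x += np.random.default_rng(3).standard_normal(n) * 5e-6
        peaks = detect_r_peaks(volts(x, label="ECG"))
        assert abs(len(peaks) - len(planted)) <= 2
        err = np.array([np.min(np.abs(peaks - p)) for p in idx / FS])
        assert np.max(err) <= 0.005

    def test_low_rate_warns(self):
        with pytest.warns(UserWarning, match="250"):
            detect_r_peaks(volts(np.zeros(1000), fs=200.0))


class TestRrIntervals:
    def test_first_differences(self):
        out = rr_intervals([0.0, 0.2, 0.4])
        assert np.allclose(out.rr_s, [0.2, 0.2])

    def test_single_peak_empty(self):
        assert len(rr_intervals([1.0]).rr_s) == 0

    def test_arrhythmic_pair(self):
        out = rr_intervals([0.0, 0.167, 0.667])
        assert np.allclose(out.rr_s, [0.167, 0.5])

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            rr_intervals([0.0, 0.5, 0.4])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-3, 2.0), min_size=1, max_size=50))
    def test_sum_rule(self, deltas):
        peaks = np.cumsum(deltas)
        out = rr_intervals(peaks)
        assert np.sum(out.rr_s) == pytest.approx(peaks[-1] - peaks[0])
        assert np.all(out.rr_s > 0)


class TestClassifySov:
    def lfp_epochs(self, freq, n_epochs=6, fs=FS, amp=200e-6):
        t = np.arange(int(n_epochs * 10 * fs)) / fs
        rng = np.random.default_rng(1)
        return volts(amp * np.sin(2 * np.pi * freq * t)
                     + 5e-6 * rng.standard_normal(len(t)))

    def acc(self, level, n_epochs=6):
        return TimeSeries(np.full(n_epochs * 10, level), 1.0, units="g")

    def test_delta_dominant_quiet_is_nrem(self):
        epochs = classify_sov(self.lfp_epochs(2.0), self.acc(0.0))
        assert all(e.state == "NREM" for e in epochs)

    def test_theta_dominant_quiet_is_rem(self):
        epochs = classify_sov(self.lfp_epochs(6.0), self.acc(0.001))
        assert all(e.state == "REM" for e in epochs)

    def test_movement_wins_regardless_of_lfp(self):
        # quiet half then sustained movement: active epochs score WAKE even
        # though the LFP stays delta-dominated throughout
        acc = TimeSeries(np.r_[np.zeros(30), np.full(30, 0.3)], 1.0, units="g")
        epochs = classify_sov(self.lfp_epochs(2.0), acc)
        assert all(e.state == "NREM" for e in epochs[:3])
        assert all(e.state == "WAKE" for e in epochs[3:])

    def test_epochs_tile_contiguously(self):
        epochs = classify_sov(self.lfp_epochs(6.0), self.acc(0.0))
        for a, b in zip(epochs, epochs[1:]):
            assert b.t_start_s == pytest.approx(a.t_end_s)

    def test_misaligned_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_sov(self.lfp_epochs(6.0),
                         TimeSeries(np.zeros(5), 1.0, t0_s=1000.0))


class TestSdPropagation:
    def ev(self, ch, onset):
        from dcemu.event_detection import SdEvent
        return SdEvent(ch, onset, onset + 40, -0.0075, -0.035, 0.0275, 40.0)

    def test_hpl_to_hal_ordering(self):
        order = sd_propagation_order([self.ev("HAL", 104.0), self.ev("HPL", 100.0)])
        assert [(c, d) for c, _, d in order] == [("HPL", 0.0), ("HAL", 4.0)]

    def test_single_channel_zero_delay(self):
        order = sd_propagation_order([self.ev("HPL", 10.0)])
        assert order == [("HPL", 10.0, 0.0)]

    def test_ties_break_on_label(self):
        order = sd_propagation_order([self.ev("B", 5.0), self.ev("A", 5.0)])
        assert [c for c, _, _ in order] == ["A", "B"]
        assert all(d == 0.0 for _, _, d in order)

    def test_empty(self):
        assert sd_propagation_order([]) == []
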
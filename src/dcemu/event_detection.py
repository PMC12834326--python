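"""Event detectors for DC-coupled rodent electrophysiology.

Four detectors operate on physical-unit traces:

* **Spreading depolarization (SD)** — on the 0.5 Hz low-passed DC-coupled
  trace, onset is the first downward crossing of a 7.5 mV drop relative to
  the value 3 s earlier; offset is the first subsequent upward crossing of
  2 mV above the onset potential.  SDs are tens-of-millivolt negative DC
  excursions lasting tens of seconds; seizure-associated DC shifts (~5 mV)
  stay below the onset threshold by design.
* **Seizure candidates + counting** — a 9-16 Hz band-power burst detector
  with hysteresis; counted events must be longer than 10 s, and events
  spaced closer than 10 min merge into a single counted event.
* **Cardiac R peaks / RR intervals** — 15-125 Hz band-pass, adaptive-
  threshold local maxima with a 60 ms refractory period; RR intervals are
  the first differences of R-peak times.
* **State of vigilance (SOV)** — epochs scored WAKE from accelerometer
  activity, REM from a 4-7 Hz theta spectral peak with low movement, NREM
  from maximal 0.5-4 Hz delta power with absent movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import TimeSeries
from .signal_conditioning import acc_rms_power, bandpass, lowpass, welch_psd

__all__ = [
    "SdDetectorParams", "SdEvent", "SeizureEvent", "RrSeries", "HypnogramEpoch",
    "detect_sd", "detect_seizure_candidates", "consolidate_seizures",
    "detect_r_peaks", "rr_intervals", "classify_sov", "sd_propagation_order",
]

WAKE, NREM, REM, UNSCORED = "WAKE", "NREM", "REM", "UNSCORED"


# ---------------------------------------------------------------------------
# spreading depolarization

@dataclass
class SdDetectorParams:
    """Thresholds of the SD detector (defaults are the printed conventions).

    ``crossing_tol_v`` is a small absolute tolerance applied to both
    threshold comparisons so that traces sitting numerically *on* a
    threshold after the zero-phase low-pass (whose DC gain carries ~1e-12
    coefficient rounding) resolve deterministically; at 1 uV it is 0.05% of
    the smallest threshold and far below physiological scales.
    """

    onset_drop_v: float = 0.0075     # 7.5 mV drop vs the value lookback_s before
    lookback_s: float = 3.0
    offset_margin_v: float = 0.002   # offset crosses onset potential + 2 mV
    lowpass_cutoff_hz: float = 0.5
    crossing_tol_v: float = 1e-6

    def __post_init__(self):
        for name in ("onset_drop_v", "lookback_s", "offset_margin_v",
                     "lowpass_cutoff_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SdEvent:
    """One detected spreading depolarization."""

    channel: str
    onset_s: float
    offset_s: float
    onset_potential_v: float
    min_potential_v: float
    amplitude_v: float          # onset_potential - min_potential
    duration_s: float
    truncated: bool = False     # offset not reached before end of trace


def detect_sd(ts: TimeSeries, params: SdDetectorParams | None = None,
              channel: str | None = None) -> list:
    """Detect spreading depolarizations on a DC-coupled trace in volts.

    The trace is low-passed at 0.5 Hz first; the 3 s look-back is an exact
    sample shift of ``round(lookback_s * fs)``.  Events whose offset is not
    reached before the end of the trace are emitted with the offset at the
    trace end and ``truncated=True`` rather than dropped.  The detector
    re-arms after each offset.
    """
    p = params or SdDetectorParams()
    fs = ts.fs_hz
    k = int(round(p.lookback_s * fs))
    if k < 1:
        raise ValueError(
            f"sampling rate {fs} Hz too low to honour the {p.lookback_s} s look-back")
    if ts.n <= k:
        raise ValueError("trace shorter than the look-back window")
    if ts.n and abs(np.mean(ts.values)) < 1e-12 < np.ptp(ts.values):
        warnings.warn("trace mean is ~0; SD detection expects a DC-coupled "
                      "(not mean-removed) signal", UserWarning)

    x = lowpass(ts, p.lowpass_cutoff_hz).values
    d = np.zeros_like(x)
    d[k:] = x[k:] - x[:-k]
    candidates = np.flatnonzero(d < -(p.onset_drop_v - p.crossing_tol_v))

    label = channel if channel is not None else ts.label
    events: list = []
    pos = 0
    n = len(x)
    while True:
        ci = np.searchsorted(candidates, pos)
        if ci >= len(candidates):
            break
        onset = int(candidates[ci])
        v_on = x[onset]
        thr = v_on + p.offset_margin_v
        above = np.flatnonzero(x[onset + 1:] >= thr - p.crossing_tol_v)
        if len(above):
            off = onset + 1 + int(above[0])
            truncated = False
        else:
            off = n - 1
            truncated = True
        vmin = float(x[onset:off + 1].min())
        events.append(SdEvent(
            channel=label,
            onset_s=ts.t0_s + onset / fs,
            offset_s=ts.t0_s + off / fs,
            onset_potential_v=float(v_on),
            min_potential_v=vmin,
            amplitude_v=float(v_on) - vmin,
            duration_s=(off - onset) / fs,
            truncated=truncated,
        ))
        pos = off + 1
    return events


def sd_propagation_order(events, group_window_s: float = 120.0) -> list:
    """Order SD onsets across channels within one episode.

    Returns ``(channel, onset_s, delay_s)`` tuples sorted by onset with the
    delay measured from the earliest onset; simultaneous onsets tie-break on
    channel label order.  ``group_window_s`` documents the episode-grouping
    span the caller should have applied.
    """
    if not events:
        return []
    ordered = sorted(events, key=lambda e: (e.onset_s, e.channel))
    first = ordered[0].onset_s
    return [(e.channel, e.onset_s, e.onset_s - first) for e in ordered]


# ---------------------------------------------------------------------------
# seizures

@dataclass
class SeizureEvent:
    """A counted seizure (after duration/spacing consolidation)."""

    onset_s: float
    offset_s: float
    duration_s: float
    channels_involved: frozenset = frozenset()


def _channel_candidates(ts: TimeSeries, band, window_s, k, baseline_s,
                        min_on, min_off) -> list:
    """Hysteresis band-power detector on one channel; local helper."""
    bp = bandpass(ts, band[0], band[1]).values
    w = int(round(ts.fs_hz * window_s))
    m = len(bp) // w
    if m == 0:
        return []
    power = (bp[: m * w] ** 2).reshape(m, w).mean(axis=1)
    base_win = max(3, int(round(baseline_s / window_s)))
    baseline = (pd.Series(power).rolling(base_win, min_periods=1)
                .median().to_numpy())
    active = power > k * np.maximum(baseline, np.finfo(float).tiny)

    out = []
    i = 0
    while i < m:
        if active[i] and (i + min_on <= m) and active[i:i + min_on].all():
            start = i
            last_active = i
            quiet = 0
            j = i
            while j < m:
                if active[j]:
                    last_active = j
                    quiet = 0
                else:
                    quiet += 1
                    if quiet >= min_off:
                        break
                j += 1
            out.append((ts.t0_s + start * window_s,
                        ts.t0_s + (last_active + 1) * window_s))
            i = j + 1
        else:
            i += 1
    return out


def detect_seizure_candidates(channels, band=(9.0, 16.0), window_s: float = 1.0,
                              k: float = 5.0, baseline_s: float = 300.0,
                              min_on: int = 2, min_off: int = 2) -> list:
    """Per-channel 9-16 Hz band-power burst candidates, merged across channels.

    A candidate begins when 1 s band power exceeds ``k`` times the rolling
    median of the trailing ``baseline_s`` baseline for at least ``min_on``
    consecutive windows, and ends after ``min_off`` consecutive windows
    below.  Overlapping per-channel intervals merge with the union of their
    channel sets.  ``channels`` maps label -> TimeSeries (a bare list of
    labelled TimeSeries is accepted too).

    Returns ``(onset_s, offset_s, channel_set)`` tuples sorted by onset.
    """
    if not isinstance(channels, dict):
        channels = {ts.label or f"ch{i}": ts for i, ts in enumerate(channels)}
    if not channels:
        raise ValueError("need at least one channel")
    for ts in channels.values():
        if ts.fs_hz <= 2 * band[1]:
            raise ValueError(
                f"sampling rate {ts.fs_hz} Hz cannot resolve the {band} Hz band")

    spans = []
    for label, ts in channels.items():
        for on, off in _channel_candidates(ts, band, window_s, k, baseline_s,
                                           min_on, min_off):
            spans.append((on, off, {label}))
    spans.sort(key=lambda s: s[0])
    merged: list = []
    for on, off, labels in spans:
        if merged and on <= merged[-1][1]:
            prev_on, prev_off, prev_labels = merged[-1]
            merged[-1] = (prev_on, max(prev_off, off), prev_labels | labels)
        else:
            merged.append((on, off, set(labels)))
    return [(on, off, frozenset(labels)) for on, off, labels in merged]


def consolidate_seizures(candidates, min_duration_s: float = 10.0,
                         min_gap_s: float = 600.0) -> list:
    """Apply the counting rule: merge candidates spaced closer than 10 min
    into one event, then discard events not longer than 10 s.

    ``candidates`` are ``(onset_s, offset_s[, channels])`` tuples sorted by
    onset; unsorted input is rejected.
    """
    cands = [tuple(c) for c in candidates]
    onsets = [c[0] for c in cands]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("candidates must be sorted by onset")

    merged: list = []
    for c in cands:
        on, off = float(c[0]), float(c[1])
        labels = set(c[2]) if len(c) > 2 else set()
        if merged and on - merged[-1][1] < min_gap_s:
            merged[-1][1] = max(merged[-1][1], off)
            merged[-1][2] |= labels
        else:
            merged.append([on, off, labels])

    events = []
    for on, off, labels in merged:
        if off - on > min_duration_s:
            events.append(SeizureEvent(on, off, off - on, frozenset(labels)))
    return events


# ---------------------------------------------------------------------------
# cardiac

@dataclass
class RrSeries:
    """R-peak times and their first differences (RR intervals)."""

    peak_times_s: np.ndarray
    rr_s: np.ndarray


def detect_r_peaks(ecg: TimeSeries, band=(15.0, 125.0),
                   refractory_s: float = 0.06, block_s: float = 2.0,
                   quantile: float = 0.995, rel_height: float = 0.5) -> np.ndarray:
    """R-wave peak times from a cardiac trace.

    The trace is band-passed at 15-125 Hz; polarity is auto-detected from
    the skewness of the filtered trace; peaks are local maxima exceeding an
    adaptive threshold (``rel_height`` times a per-block upper quantile,
    floored at 4 robust SDs), with a 60 ms refractory period supporting rat
    rates up to 1000 bpm.
    """
    fs = ecg.fs_hz
    if fs < 250:
        warnings.warn(f"sampling rate {fs} Hz is below the recommended 250 Hz "
                      "for R-peak timing", UserWarning)
    y = bandpass(ecg, band[0], min(band[1], fs / 2 * 0.99)).values
    if len(y) == 0:
        return np.array([])
    if stats.skew(y) < 0:
        y = -y

    w = max(1, int(round(block_s * fs)))
    m = max(1, int(np.ceil(len(y) / w)))
    padded = np.pad(y, (0, m * w - len(y)), mode="edge")
    block_q = np.quantile(padded.reshape(m, w), quantile, axis=1)
    thr = np.repeat(rel_height * block_q, w)[: len(y)]
    mad = np.median(np.abs(y - np.median(y)))
    thr = np.maximum(thr, 4 * 1.4826 * mad)

    idx, _ = sps.find_peaks(y, distance=max(1, int(round(refractory_s * fs))))
    idx = idx[y[idx] >= thr[idx]]
    return ecg.t0_s + idx / fs


def rr_intervals(peaks) -> RrSeries:
    """RR intervals as the first difference of R-peak times."""
    peaks = np.asarray(peaks, dtype=np.float64)
    if len(peaks) >= 2 and np.any(np.diff(peaks) <= 0):
        raise ValueError("peak times must be strictly increasing")
    return RrSeries(peak_times_s=peaks, rr_s=np.diff(peaks))


# ---------------------------------------------------------------------------
# state of vigilance

@dataclass
class HypnogramEpoch:
    t_start_s: float
    t_end_s: float
    state: str


def classify_sov(hippocampal_lfp: TimeSeries, acc_power: TimeSeries,
                 epoch_s: float = 10.0, r_rem: float = 1.5,
                 wake_factor: float = 3.0, wake_quantile: float = 0.2,
                 wake_floor_g: float = 0.02) -> list:
    """Score vigilance states on fixed epochs.

    Per epoch: WAKE if the median windowed acceleration power exceeds the
    wake threshold (``wake_factor`` times the session's ``wake_quantile``
    quantile of acceleration power, floored at ``wake_floor_g``); otherwise
    REM if the theta (4-7 Hz) / delta (0.5-4 Hz) band-power ratio of the
    hippocampal LFP exceeds ``r_rem`` and the spectral argmax over
    0.5-12 Hz lies in theta; otherwise NREM if the argmax lies in delta;
    otherwise UNSCORED.  Epochs tile the common span contiguously.
    """
    start = max(hippocampal_lfp.t0_s, acc_power.t0_s)
    stop = min(hippocampal_lfp.end_s, acc_power.end_s)
    if stop - start < epoch_s:
        raise ValueError("inputs do not share at least one epoch of overlap")

    wake_thr = max(wake_factor * float(np.quantile(acc_power.values, wake_quantile)),
                   wake_floor_g)
    n_epochs = int((stop - start) / epoch_s)
    epochs = []
    for e in range(n_epochs):
        t0, t1 = start + e * epoch_s, start + (e + 1) * epoch_s
        acc_med = float(np.median(acc_power.segment(t0, t1).values))
        if acc_med > wake_thr:
            epochs.append(HypnogramEpoch(t0, t1, WAKE))
            continue
        seg = hippocampal_lfp.segment(t0, t1)
        psd = welch_psd(seg, window_samples=min(2048, seg.n))
        theta = psd.band_power(4.0, 7.0)
        delta = psd.band_power(0.5, 4.0)
        peak = psd.peak_freq(0.5, 12.0)
        if delta > 0 and theta / delta > r_rem and 4.0 <= peak <= 7.0:
            state = REM
        elif 0.5 <= peak <= 4.0:
            state = NREM
        else:
            state = UNSCORED
        epochs.append(HypnogramEpoch(t0, t1, state))
    return epochs
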
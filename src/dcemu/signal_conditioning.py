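"""Filtering, spectral, and windowed-power primitives.

Conventions used throughout the toolkit, matching the analysis pipeline the
detectors were designed for:

* Band limits: LFP/ECoG at 0.5-125 Hz; acceleration at 2-125 Hz; cardiac at
  15-125 Hz; near-DC traces low-passed at 0.5 Hz.
* All filters are 4th-order Butterworth applied forward-backward
  (``sosfiltfilt``), i.e. zero phase, so event onset times are preserved.
* Average power spectra use Welch's method with a 2048-sample Hann window at
  50% overlap.
* Spectrograms and acceleration power use consecutive non-overlapping 1 s
  windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import TimeSeries

__all__ = [
    "Spectrum", "Spectrogram",
    "bandpass", "lowpass", "highpass",
    "welch_psd", "spectrogram", "acc_rms_power",
]

DEFAULT_ORDER = 4


@dataclass
class Spectrum:
    """A one-sided power spectral density (units^2 / Hz)."""

    freqs_hz: np.ndarray
    power: np.ndarray
    window_len_samples: int
    method_tag: str = "welch-hann-50%"

    def __post_init__(self):
        if len(self.freqs_hz) != len(self.power):
            raise ValueError("freqs_hz and power must have equal length")

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Integrated power over [lo_hz, hi_hz] (trapezoid rule)."""
        mask = (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.power[mask], self.freqs_hz[mask]))

    def peak_freq(self, lo_hz: float = 0.0, hi_hz: float = np.inf) -> float:
        """Frequency of the largest PSD bin within [lo_hz, hi_hz]."""
        mask = (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)
        idx = np.flatnonzero(mask)
        return float(self.freqs_hz[idx[np.argmax(self.power[idx])]])


@dataclass
class Spectrogram:
    """Time-frequency power on consecutive windows (time x frequency)."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray
    window_s: float

    def __post_init__(self):
        if self.power.shape != (len(self.times_s), len(self.freqs_hz)):
            raise ValueError("power must be (n_times, n_freqs)")


def _design_sos(lo_hz: float, hi_hz: float, fs_hz: float, order: int):
    """Butterworth SOS for a (possibly degenerate) band; None = all-pass."""
    nyq = fs_hz / 2.0
    lo = float(lo_hz) if lo_hz is not None else 0.0
    hi = float(hi_hz) if hi_hz is not None else np.inf
    if lo < 0 or hi <= lo:
        raise ValueError(f"need 0 <= lo < hi, got ({lo_hz}, {hi_hz})")
    if lo >= nyq or (np.isfinite(hi) and hi >= nyq):
        raise ValueError(f"band ({lo_hz}, {hi_hz}) Hz outside Nyquist {nyq} Hz")
    if lo == 0 and not np.isfinite(hi):
        return None
    if lo == 0:
        return sps.butter(order, hi, btype="lowpass", fs=fs_hz, output="sos")
    if not np.isfinite(hi):
        return sps.butter(order, lo, btype="highpass", fs=fs_hz, output="sos")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def bandpass(ts: TimeSeries, lo_hz: float, hi_hz: float,
             order: int = DEFAULT_ORDER) -> TimeSeries:
    """Zero-phase band-pass; ``lo_hz = 0`` degenerates to low-pass and
    ``hi_hz = inf`` to high-pass.  Output length equals input length and
    units are preserved."""
    sos = _design_sos(lo_hz, hi_hz, ts.fs_hz, order)
    if sos is None:
        return ts.with_values(ts.values.copy())
    return ts.with_values(sps.sosfiltfilt(sos, ts.values))


def lowpass(ts: TimeSeries, cutoff_hz: float, order: int = DEFAULT_ORDER) -> TimeSeries:
    return bandpass(ts, 0.0, cutoff_hz, order=order)


def highpass(ts: TimeSeries, cutoff_hz: float, order: int = DEFAULT_ORDER) -> TimeSeries:
    return bandpass(ts, cutoff_hz, np.inf, order=order)


def welch_psd(ts: TimeSeries, window_samples: int = 2048) -> Spectrum:
    """Welch-averaged PSD: Hann taper, 50% overlap, ``fs/window`` resolution."""
    if ts.n < window_samples:
        raise ValueError(
            f"input ({ts.n} samples) shorter than the {window_samples}-sample window")
    freqs, power = sps.welch(ts.values, fs=ts.fs_hz, window="hann",
                             nperseg=window_samples,
                             noverlap=window_samples // 2,
                             detrend="constant")
    return Spectrum(freqs, power, window_samples)


def _window_periodograms(x: np.ndarray, fs: float, w: int) -> tuple:
    """Hann periodogram of each consecutive non-overlapping length-w window."""
    m = len(x) // w
    segs = x[: m * w].reshape(m, w)
    win = sps.get_window("hann", w)
    scale = 1.0 / (fs * np.sum(win ** 2))
    spec = np.fft.rfft(segs * win, axis=1)
    power = (spec.real ** 2 + spec.imag ** 2) * scale
    if w % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    return freqs, power


def spectrogram(ts: TimeSeries, window_s: float = 1.0) -> Spectrogram:
    """Consecutive non-overlapping windows; each column a Hann periodogram.

    Window times are window centres.
    """
    w = int(round(ts.fs_hz * window_s))
    if w < 8:
        raise ValueError("window must span at least 8 samples")
    if ts.n < w:
        raise ValueError("input shorter than one window")
    freqs, power = _window_periodograms(ts.values, ts.fs_hz, w)
    m = power.shape[0]
    times = ts.t0_s + (np.arange(m) + 0.5) * window_s
    return Spectrogram(times, freqs, power, window_s)


def acc_rms_power(acc, window_s: float = 1.0, band=(2.0, 125.0)) -> TimeSeries:
    """Windowed RMS of the band-filtered three-axis acceleration magnitude.

    Per window the output is ``sqrt(mean(x^2 + y^2 + z^2))`` after each axis
    passes the 2-125 Hz band (static gravity offsets are removed by the
    2 Hz high edge).  One output sample per window, sampled at ``1/window_s``.
    """
    ax, ay, az = acc
    if not (ax.n == ay.n == az.n):
        raise ValueError("acceleration axes must have equal length")
    if not (ax.fs_hz == ay.fs_hz == az.fs_hz):
        raise ValueError("acceleration axes must share one sampling rate")
    hi = min(band[1], ax.fs_hz / 2 * 0.99)   # clip to Nyquist for low rates
    sq = np.zeros(ax.n)
    for axis in (ax, ay, az):
        sq += bandpass(axis, band[0], hi).values ** 2
    w = int(round(ax.fs_hz * window_s))
    m = len(sq) // w
    rms = np.sqrt(sq[: m * w].reshape(m, w).mean(axis=1))
    return TimeSeries(rms, fs_hz=1.0 / window_s, t0_s=ax.t0_s,
                      units=ax.units, label="acc_rms")
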
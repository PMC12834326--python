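"""Video/electrophysiology synchronization check via dual actigraphy.

Two independent movement measures are reduced to 1 s windows: a video-based
actigraphy (mean absolute first time-derivative of frame pixel intensity)
and an accelerometer-based actigraphy (windowed RMS of the band-filtered
head acceleration).  Both are high-pass filtered at 10 mHz to strip slow
illumination/posture drifts and cross-correlated; on a synchronized rig the
normalized cross-correlation peaks at lag 0 +- 1 s, and a planted clock
offset appears as a shifted peak.  The 1 s windows make sub-second lag
resolution impossible, hence the +-1 window acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import TimeSeries
from .signal_conditioning import acc_rms_power

__all__ = ["ActigraphySeries", "video_actigraphy", "video_actigraphy_frames",
           "accel_actigraphy", "sync_lag"]

VIDEO, ACCEL = "VIDEO", "ACCEL"


@dataclass
class ActigraphySeries:
    """Movement intensity, one nonnegative value per window."""

    values: np.ndarray
    window_s: float = 1.0
    t0_s: float = 0.0
    source: str = VIDEO

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n(self) -> int:
        return len(self.values)


def video_actigraphy(frame_intensity: TimeSeries,
                     window_s: float = 1.0) -> ActigraphySeries:
    """Actigraphy from a frame-mean intensity series.

    Per window: the mean of ``|I(f) - I(f-1)|`` over the frames in the
    window (the first frame of the recording contributes no derivative).
    """
    fs = frame_intensity.fs_hz
    fpw = int(round(fs * window_s))
    if fpw < 2:
        raise ValueError(
            f"frame rate {fs} Hz gives fewer than 2 frames per {window_s} s window")
    d = np.abs(np.diff(frame_intensity.values, prepend=frame_intensity.values[:1]))
    m = len(d) // fpw
    vals = d[: m * fpw].reshape(m, fpw).mean(axis=1)
    return ActigraphySeries(vals, window_s=window_s, t0_s=frame_intensity.t0_s,
                            source=VIDEO)


def video_actigraphy_frames(frames: np.ndarray, frame_rate_hz: float,
                            window_s: float = 1.0,
                            t0_s: float = 0.0) -> ActigraphySeries:
    """Full-frame variant: the absolute inter-frame derivative is averaged
    over pixels first, then over the frames in each window.

    ``frames`` is a (n_frames, height, width) stack.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n_frames, height, width) stack")
    per_frame = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    per_frame = np.concatenate([[0.0], per_frame])
    series = TimeSeries(per_frame, fs_hz=frame_rate_hz, t0_s=t0_s,
                        units="a.u.", label="frame|dI|")
    fpw = int(round(frame_rate_hz * window_s))
    if fpw < 2:
        raise ValueError("fewer than 2 frames per window")
    m = len(per_frame) // fpw
    vals = per_frame[: m * fpw].reshape(m, fpw).mean(axis=1)
    return ActigraphySeries(vals, window_s=window_s, t0_s=t0_s, source=VIDEO)


def accel_actigraphy(acc, window_s: float = 1.0) -> ActigraphySeries:
    """Actigraphy from the head-mounted accelerometer (delegates to the
    windowed RMS acceleration power)."""
    rms = acc_rms_power(acc, window_s=window_s)
    return ActigraphySeries(rms.values, window_s=window_s, t0_s=rms.t0_s,
                            source=ACCEL)


def sync_lag(a: ActigraphySeries, b: ActigraphySeries,
             max_lag_s: float = 120.0, highpass_hz: float = 0.01,
             return_function: bool = False):
    """Normalized cross-correlation lag between two actigraphy series.

    Both series are high-passed at ``highpass_hz`` (first-order Butterworth,
    forward-backward), mean-removed, and Pearson-correlated at every integer
    window lag with ``|lag| <= max_lag_s``.  Returns ``(lag_s,
    peak_correlation)``; a positive lag means ``b`` lags ``a``.  With
    ``return_function=True`` a third element ``(lags_s, corr)`` carries the
    full correlation function for reporting.
    """
    if a.window_s != b.window_s:
        raise ValueError("actigraphy series must share one window length")
    fs = 1.0 / a.window_s
    ia0 = int(round(a.t0_s * fs))
    ib0 = int(round(b.t0_s * fs))
    lo = max(ia0, ib0)
    hi = min(ia0 + a.n, ib0 + b.n)
    if (hi - lo) / fs < 10.0 * max_lag_s:
        raise ValueError(
            f"overlap of {(hi - lo) / fs:.0f} s is shorter than 10 x max_lag "
            f"({10 * max_lag_s:.0f} s)")
    xa = a.values[lo - ia0: hi - ia0]
    xb = b.values[lo - ib0: hi - ib0]

    sos = sps.butter(1, highpass_hz, btype="highpass", fs=fs, output="sos")
    xa = sps.sosfiltfilt(sos, xa)
    xb = sps.sosfiltfilt(sos, xb)
    xa = xa - xa.mean()
    xb = xb - xb.mean()

    L = int(round(max_lag_s * fs))
    lags = np.arange(-L, L + 1)
    corr = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            u, v = xa[: len(xa) - lag], xb[lag:]
        else:
            u, v = xa[-lag:], xb[: len(xb) + lag]
        denom = np.sqrt(np.sum((u - u.mean()) ** 2) * np.sum((v - v.mean()) ** 2))
        corr[i] = 0.0 if denom == 0 else float(
            np.sum((u - u.mean()) * (v - v.mean())) / denom)
    best = int(np.argmax(corr))
    if return_function:
        return lags[best] / fs, float(corr[best]), (lags / fs, corr)
    return lags[best] / fs, float(corr[best])
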
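"""Uniformly sampled time series container shared by every module.

All signals in the toolkit — biopotentials in volts, head acceleration in g,
amperometric current in nanoamperes, video frame intensity in arbitrary units —
travel as :class:`TimeSeries`: a value array plus a sampling rate, a start-time
offset from the recording/session origin, a unit string, and a channel label.
Sample ``n`` sits at time ``t0_s + n / fs_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Sample values; converted to a float64 numpy array.
    fs_hz : float
        Sampling rate in Hz; must be positive.
    t0_s : float
        Time of the first sample, in seconds from the file/session start.
    units : str
        Physical units of the samples (``"V"``, ``"g"``, ``"nA"``, ...).
    label : str
        Channel label (``"HPL"``, ``"ECG"``, ...).
    """

    values: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    @property
    def end_s(self) -> float:
        """Time just past the last sample."""
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.fs_hz

    def with_values(self, values: np.ndarray, **meta) -> "TimeSeries":
        """Copy of this series with new samples (and optionally new metadata)."""
        out = replace(self, values=np.asarray(values, dtype=np.float64))
        for key, val in meta.items():
            setattr(out, key, val)
        return out

    def index_at(self, t_s: float) -> int:
        """Index of the sample nearest to absolute time ``t_s`` (clipped)."""
        idx = int(round((t_s - self.t0_s) * self.fs_hz))
        return min(max(idx, 0), self.n - 1)

    def segment(self, start_s: float, stop_s: float) -> "TimeSeries":
        """Sub-series covering ``[start_s, stop_s)`` in absolute time."""
        i0 = max(0, int(np.ceil((start_s - self.t0_s) * self.fs_hz - 1e-9)))
        i1 = min(self.n, int(np.ceil((stop_s - self.t0_s) * self.fs_hz - 1e-9)))
        i1 = max(i1, i0)
        return TimeSeries(self.values[i0:i1], self.fs_hz,
                          t0_s=self.t0_s + i0 / self.fs_hz,
                          units=self.units, label=self.label)
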
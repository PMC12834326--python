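"""Floating-potentiostat arithmetic, stimulus waveforms, and CPA oxygen sensing.

The recording rig carries a floating three-electrode potentiostat: the
counter electrode is grounded, the reference potential floats, and the
working-electrode current is inferred from the voltage drop across a sense
resistor, ``i = (V1 - V2) / R``.  A DAC-driven function generator supplies
the control potential for five voltammetry waveforms: constant-potential
amperometry (CPA), fast-scan cyclic voltammetry (FSCV), long-term pulse
voltammetry (LTPV), differential pulse voltammetry (DPV), and a sinusoid
riding on a DC potential.

Oxygen sensing uses CPA at a -0.65 V bias: dissolved O2 reduction current is
proportional to concentration over the physiological range, so calibration
is a linear fit of summary currents against stoichiometrically diluted O2
concentrations between ~0.09 mM/L (tissue) and ~0.23 mM/L (arterial).  Each
calibration point is the mean of the middle 80 s of a ~5 min recording,
excluding the mixing transients at either end.  In vivo CPA traces are
low-passed at 1 Hz and downsampled from 1 kHz to 20 Hz before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import TimeSeries
from .signal_conditioning import lowpass

__all__ = [
    "PotentiostatReading", "WaveformSpec", "O2CalibrationResult",
    "potentiostat_current", "generate_waveform", "cpa_point_value",
    "mix_o2_concentration", "fit_o2_calibration", "process_invivo_cpa",
    "state_conditioned_cpa_means",
]

WAVEFORM_KINDS = ("CPA", "FSCV", "LTPV", "DPV", "SINE_DC")

_REQUIRED_PARAMS = {
    "CPA": ("hold_v",),
    "FSCV": ("v_min", "v_max", "scan_rate_v_per_s"),
    "LTPV": ("base_v", "pulse_v", "pulse_s", "period_s"),
    "DPV": ("start_v", "end_v", "step_v", "pulse_amp_v", "pulse_s", "period_s"),
    "SINE_DC": ("dc_v", "amp_v", "freq_hz"),
}


def potentiostat_current(v1_v: float, v2_v: float, r_ohm: float) -> float:
    """Sense-resistor current: ``(v1 - v2) / r``; positive when point 1 is
    above point 2."""
    if not r_ohm > 0:
        raise ValueError("sense resistance must be positive")
    return (v1_v - v2_v) / r_ohm


@dataclass(frozen=True)
class PotentiostatReading:
    """One current reading derived from the two sense-point potentials."""

    v1_v: float
    v2_v: float
    r_ohm: float

    @property
    def current_a(self) -> float:
        return potentiostat_current(self.v1_v, self.v2_v, self.r_ohm)


@dataclass
class WaveformSpec:
    """Control-potential waveform description for the function generator."""

    kind: str
    duration_s: float
    update_rate_hz: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in WAVEFORM_KINDS:
            raise ValueError(f"unknown waveform kind {self.kind!r}; "
                             f"choose from {WAVEFORM_KINDS}")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.update_rate_hz > 0:
            raise ValueError("update_rate_hz must be positive")
        missing = [k for k in _REQUIRED_PARAMS[self.kind] if k not in self.params]
        if missing:
            raise ValueError(f"{self.kind} waveform missing params: {missing}")
        p = self.params
        if self.kind == "FSCV":
            if not p["v_min"] < p["v_max"]:
                raise ValueError("FSCV requires v_min < v_max")
            if not p["scan_rate_v_per_s"] > 0:
                raise ValueError("FSCV scan rate must be positive")
        if self.kind in ("LTPV", "DPV"):
            if not 0 < p["pulse_s"] < p["period_s"]:
                raise ValueError("need 0 < pulse_s < period_s")
        if self.kind == "DPV" and p["step_v"] == 0:
            raise ValueError("DPV step_v must be nonzero")
        if self.kind == "SINE_DC" and not p["freq_hz"] > 0:
            raise ValueError("SINE_DC freq_hz must be positive")


def _phase(n: int, rate: float, period: float) -> np.ndarray:
    """Time within the current period for each sample.

    Uses integer-sample modulo when the period is commensurate with the
    update rate, so discontinuous waveforms (pulse/staircase edges) repeat
    bit-exactly instead of jittering with float-mod rounding.
    """
    pn = period * rate
    if abs(pn - round(pn)) < 1e-9 and round(pn) >= 1:
        return (np.arange(n) % int(round(pn))) / rate
    return np.mod(np.arange(n) / rate, period)


def generate_waveform(spec: WaveformSpec) -> TimeSeries:
    """Sample the control potential Vc at the DAC update rate."""
    n = int(round(spec.duration_s * spec.update_rate_hz))
    t = np.arange(n) / spec.update_rate_hz
    p = spec.params

    if spec.kind == "CPA":
        v = np.full(n, float(p["hold_v"]))
    elif spec.kind == "FSCV":
        span = p["v_max"] - p["v_min"]
        period = 2.0 * span / p["scan_rate_v_per_s"]
        tau = _phase(n, spec.update_rate_hz, period)
        half = period / 2.0
        v = np.where(tau < half,
                     p["v_min"] + p["scan_rate_v_per_s"] * tau,
                     p["v_max"] - p["scan_rate_v_per_s"] * (tau - half))
    elif spec.kind == "LTPV":
        tau = _phase(n, spec.update_rate_hz, p["period_s"])
        v = np.where(tau < p["pulse_s"], float(p["pulse_v"]), float(p["base_v"]))
    elif spec.kind == "DPV":
        n_steps = int(abs((p["end_v"] - p["start_v"]) / p["step_v"]))
        step_idx = np.minimum((t / p["period_s"]).astype(int), max(n_steps, 0))
        base = p["start_v"] + step_idx * p["step_v"]
        tau = _phase(n, spec.update_rate_hz, p["period_s"])
        # pulse applied during the final pulse_s of each staircase tread
        v = base + np.where(tau >= p["period_s"] - p["pulse_s"],
                            float(p["pulse_amp_v"]), 0.0)
    else:  # SINE_DC
        v = p["dc_v"] + p["amp_v"] * np.sin(2 * np.pi * p["freq_hz"] * t)

    return TimeSeries(v, fs_hz=spec.update_rate_hz, units="V",
                      label=f"Vc/{spec.kind}")


def cpa_point_value(current: TimeSeries) -> float:
    """Summary current of one calibration recording: mean of the centred
    80 s window ``[T/2 - 40 s, T/2 + 40 s]``, excluding mixing transients."""
    T = current.duration_s
    if T < 80.0:
        raise ValueError(f"recording of {T:.1f} s is shorter than the 80 s window")
    mid = current.t0_s + T / 2.0
    seg = current.segment(mid - 40.0, mid + 40.0)
    return float(np.mean(seg.values))


def mix_o2_concentration(v_air_ml: float, v_n2_ml: float,
                         c_air_sat_mm: float = 0.23) -> float:
    """O2 concentration after diluting air-saturated solution with
    N2-saturated (zero-O2) solution: ideal mass balance
    ``c = c_sat * v_air / (v_air + v_n2)``.

    The default air-saturated concentration anchors the top of the
    physiological calibration range (~0.23 mM/L, arterial).
    """
    if v_air_ml < 0 or v_n2_ml < 0:
        raise ValueError("volumes must be nonnegative")
    total = v_air_ml + v_n2_ml
    if total == 0:
        raise ValueError("at least one volume must be positive")
    return c_air_sat_mm * v_air_ml / total


@dataclass
class O2CalibrationResult:
    """Linear oxygen-electrode calibration over the physiological range."""

    slope_na_per_mm: float
    intercept_na: float
    r2: float
    fit_range_mm: tuple = (0.09, 0.23)
    n_points: int = 0


def fit_o2_calibration(points, fit_range=(0.09, 0.23)) -> O2CalibrationResult:
    """Ordinary least squares of current (nA) on concentration (mM/L),
    restricted to points inside ``fit_range``; needs at least 3 in-range
    points."""
    pts = [(float(c), float(i)) for c, i in points]
    inside = [(c, i) for c, i in pts if fit_range[0] <= c <= fit_range[1]]
    if len(inside) < 3:
        raise ValueError(
            f"need >= 3 calibration points inside {fit_range} mM/L, "
            f"got {len(inside)}")
    conc = np.array([c for c, _ in inside])
    curr = np.array([i for _, i in inside])
    fit = stats.linregress(conc, curr)
    return O2CalibrationResult(
        slope_na_per_mm=float(fit.slope),
        intercept_na=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        fit_range_mm=tuple(fit_range),
        n_points=len(inside),
    )


def process_invivo_cpa(current: TimeSeries, target_fs_hz: float = 20.0,
                       lowpass_hz: float = 1.0) -> TimeSeries:
    """In vivo CPA post-processing: 1 Hz low-pass, then stride decimation
    from 1 kHz to 20 Hz.

    The 1 Hz anti-alias cutoff sits far below the 10 Hz output Nyquist, so
    a simple stride after the low-pass is exact enough; the decimation
    factor scales if the input is not at 1 kHz (with a warning).
    """
    if current.fs_hz != 1000.0:
        warnings.warn(f"expected a 1000 Hz CPA trace, got {current.fs_hz} Hz; "
                      "scaling the decimation factor", UserWarning)
    factor = max(1, int(round(current.fs_hz / target_fs_hz)))
    smooth = lowpass(current, lowpass_hz).values
    return TimeSeries(smooth[::factor], fs_hz=current.fs_hz / factor,
                      t0_s=current.t0_s, units=current.units,
                      label=current.label)


def _bouts_from_hypnogram(hypnogram) -> list:
    """Merge contiguous same-state epochs into (start, end, state) bouts."""
    bouts = []
    for ep in hypnogram:
        if bouts and bouts[-1][2] == ep.state and abs(bouts[-1][1] - ep.t_start_s) < 1e-9:
            bouts[-1] = (bouts[-1][0], ep.t_end_s, ep.state)
        else:
            bouts.append((ep.t_start_s, ep.t_end_s, ep.state))
    return bouts


def state_conditioned_cpa_means(cpa: TimeSeries, hypnogram, exclusion_events=(),
                                margin_s: float = 60.0) -> dict:
    """Mean CPA current per vigilance state over clean bouts.

    Bouts intersecting ``[event_onset - margin_s, event_offset + margin_s]``
    of any exclusion event (seizure or SD) are discarded.  Exclusion events
    may be objects with ``onset_s``/``offset_s`` or ``(onset, offset)``
    pairs.  Returns ``state -> (mean_current, bout_count)``; states with no
    clean bouts are absent.
    """
    exc = []
    for ev in exclusion_events:
        if hasattr(ev, "onset_s"):
            exc.append((ev.onset_s - margin_s, ev.offset_s + margin_s))
        else:
            exc.append((ev[0] - margin_s, ev[1] + margin_s))

    sums: dict = {}
    for start, end, state in _bouts_from_hypnogram(hypnogram):
        if any(start < e_hi and end > e_lo for e_lo, e_hi in exc):
            continue
        seg = cpa.segment(start, end)
        if seg.n == 0:
            continue
        tot, cnt, bouts = sums.get(state, (0.0, 0, 0))
        sums[state] = (tot + float(seg.values.sum()), cnt + seg.n, bouts + 1)
    return {state: (tot / cnt, bouts) for state, (tot, cnt, bouts) in sums.items()}
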
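"""Seeded synthetic multimodal session generator with ground truth.

Emulates the phenomenology of a DC-sensitive rodent EMU session well enough
to exercise every detector in the toolkit without hardware:

* **LFP/ECoG** — state-dependent background (NREM: delta-band noise; REM:
  6 Hz theta rhythm; WAKE: broadband noise) plus seizure bursts (a sentinel
  spike, then a 9-16 Hz oscillation riding on a ~5 mV negative DC shift)
  and spreading-depolarization waveforms (raised-cosine fall to tens of
  negative millivolts, plateau, exponential recovery, per-channel
  propagation delays).
* **Head acceleration** — movement bouts during WAKE, brief twitches in
  REM, quiescence in NREM, convulsive bursts during seizures, plus a 1 g
  gravity offset on z.
* **ECG** — an R-peak impulse train (rat-typical 360 bpm) convolved with a
  narrow QRS kernel, with optional planted long-RR arrhythmia intervals.
* **CPA current** — per-state mean current (REM above NREM, matching the
  oxygen-delivery direction) plus AR(1) noise.
* **Video intensity** — baseline plus movement-coupled fluctuations,
  optionally delayed by a planted clock skew.

All randomness flows from one master seed through per-modality substreams,
so adding a modality never perturbs the others, and the same seed always
reproduces the session bit for bit.  Every planted event is logged in a
:class:`GroundTruthLog` against which detectors are scored.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import TimeSeries
from . import stream_format as sf

__all__ = [
    "SeizureSpec", "SdSpec", "EcgSpec", "CpaSpec", "VideoSpec",
    "ScenarioConfig", "GroundTruthLog", "Session", "ExportResult",
    "simulate_session", "export_session", "scenario_from_dict",
]

WAKE, NREM, REM = "WAKE", "NREM", "REM"

# LFP background amplitudes (volts, std or sine amplitude).  A broadband
# floor common to all states keeps 9-16 Hz power state-independent (wake is
# low-voltage desynchronized); rhythms ride on top of it per state.
_BROADBAND_FLOOR_V = 50e-6
_BROADBAND_BAND_HZ = (0.5, 45.0)
_WHITE_FLOOR_V = 5e-6
_NREM_DELTA_V = 150e-6
_REM_THETA_V = 200e-6
_REM_THETA_HZ = 6.0

_SD_FALL_S = 6.0          # raised-cosine fall time of the SD excursion
_SD_RECOVERY_TAU_S = 4.0  # exponential recovery time constant

# movement envelope (g): wake carries continuous low-level activity
# (grooming, posture shifts) with locomotor bouts from a per-second Markov
# process on top; REM has sparse brief twitches; NREM is quiescent;
# seizures drive convulsive bursts.
_WAKE_BASE_ACT = 0.04
_WAKE_P_START = 0.3
_WAKE_P_STOP = 0.2
_WAKE_AMP_RANGE = (0.05, 0.3)
_REM_TWITCH_P = 0.05
_REM_TWITCH_AMP = 0.004
_SEIZURE_MOVEMENT_AMP = 0.5


@dataclass
class SeizureSpec:
    onset_s: float
    duration_s: float
    burst_freq_hz: float = 12.0
    amplitude_v: float = 5e-4
    dc_shift_v: float = 0.005   # seizure-associated DC shifts are ~5 mV

    def validate(self, duration_s: float) -> None:
        if not 0 <= self.onset_s < self.onset_s + self.duration_s <= duration_s:
            raise ValueError(f"seizure at {self.onset_s}s outside the session")
        if not 9.0 <= self.burst_freq_hz <= 16.0:
            raise ValueError("burst_freq_hz must lie in the 9-16 Hz band")
        if not self.amplitude_v > 0:
            raise ValueError("seizure amplitude_v must be positive")
        if self.dc_shift_v < 0:
            raise ValueError("dc_shift_v must be nonnegative")


@dataclass
class SdSpec:
    onset_s: float
    amplitude_v: float = 0.035      # negative DC shifts reach 35 mV or more
    duration_s: float = 45.0        # onset-to-recovery-start, ~30-60 s
    channel_delays_s: dict | None = None  # label -> propagation delay

    def validate(self, duration_s: float, channels) -> None:
        if not 0 <= self.onset_s < duration_s:
            raise ValueError(f"SD at {self.onset_s}s outside the session")
        if not self.amplitude_v >= 0.02:
            raise ValueError("SD amplitude_v must be at least 20 mV (physiologic)")
        if not 30.0 <= self.duration_s <= 60.0:
            raise ValueError("SD duration_s must lie in 30-60 s")
        if self.channel_delays_s is not None:
            unknown = set(self.channel_delays_s) - set(channels)
            if unknown:
                raise ValueError(f"SD delays name unknown channels {unknown}")

    def delays_for(self, channels) -> dict:
        if self.channel_delays_s is not None:
            return dict(self.channel_delays_s)
        return {ch: 1.5 * i for i, ch in enumerate(channels)}


@dataclass
class EcgSpec:
    rate_hz: float = 6.0            # 360 bpm, rat-typical
    amplitude_v: float = 5e-4
    rr_jitter: float = 0.02         # fractional beat-to-beat variability
    noise_v: float = 5e-6
    arrhythmia: tuple = ()          # (approx_time_s, long_rr_s) pairs

    def validate(self, duration_s: float) -> None:
        if not self.rate_hz > 0:
            raise ValueError("ECG rate_hz must be positive")
        for t, rr in self.arrhythmia:
            if not 0 <= t < duration_s:
                raise ValueError(f"arrhythmia at {t}s outside the session")
            if not rr > 0:
                raise ValueError("arrhythmia RR must be positive")


@dataclass
class CpaSpec:
    state_mean_na: dict = field(default_factory=lambda: {
        WAKE: 49.0, NREM: 50.0, REM: 52.0})
    noise_na: float = 0.2
    ar_coef: float = 0.95

    def validate(self) -> None:
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.noise_na < 0:
            raise ValueError("noise_na must be nonnegative")


@dataclass
class VideoSpec:
    frame_rate_hz: float = 20.0
    gain: float = 40.0
    baseline: float = 120.0
    noise_sd: float = 0.3

    def validate(self) -> None:
        if not self.frame_rate_hz >= 2:
            raise ValueError("frame_rate_hz must be at least 2")


@dataclass
class ScenarioConfig:
    """Scenario for one synthetic session; ``seed`` is mandatory for
    reproducibility."""

    duration_s: float
    seed: int
    fs_hz: float = 1000.0
    channels: tuple = ("HPL", "HAL", "HAR", "HPR")
    sov_schedule: tuple | None = None   # (state, duration_s) bouts, or None
    seizures: tuple = ()
    sds: tuple = ()
    ecg: EcgSpec = field(default_factory=EcgSpec)
    cpa: CpaSpec = field(default_factory=CpaSpec)
    video: VideoSpec = field(default_factory=VideoSpec)
    clock_skew_s: float = 0.0

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        if not self.fs_hz > 0 or abs(self.fs_hz - round(self.fs_hz)) > 1e-9:
            raise ValueError("fs_hz must be a positive integer rate")
        self.channels = tuple(self.channels)
        if not self.channels:
            raise ValueError("at least one LFP channel is required")
        self.seizures = tuple(self.seizures)
        self.sds = tuple(self.sds)
        for sz in self.seizures:
            sz.validate(self.duration_s)
        for sd in self.sds:
            sd.validate(self.duration_s, self.channels)
        self.ecg.validate(self.duration_s)
        self.cpa.validate()
        self.video.validate()
        if self.sov_schedule is not None:
            sched = tuple((str(s).upper(), float(d)) for s, d in self.sov_schedule)
            for state, dur in sched:
                if state not in (WAKE, NREM, REM):
                    raise ValueError(f"unknown SOV state {state!r}")
                if not dur > 0:
                    raise ValueError("SOV bout durations must be positive")
            self.sov_schedule = sched


@dataclass
class GroundTruthLog:
    """Planted-event ledger for scoring every detector."""

    seizures: list            # (onset_s, offset_s)
    sds: dict                 # channel -> [{onset_s, offset_s, amplitude_v}]
    sov_epochs: list          # (start_s, end_s, state) bouts
    r_peak_times_s: np.ndarray
    cpa_state_means_na: dict
    clock_skew_s: float

    def state_at(self, t_s: float) -> str:
        for start, end, state in self.sov_epochs:
            if start <= t_s < end:
                return state
        return self.sov_epochs[-1][2] if self.sov_epochs else "UNSCORED"

    def to_dict(self) -> dict:
        return {
            "seizures": [list(s) for s in self.seizures],
            "sds": {ch: list(evs) for ch, evs in self.sds.items()},
            "sov_epochs": [list(e) for e in self.sov_epochs],
            "r_peak_times_s": np.asarray(self.r_peak_times_s).tolist(),
            "cpa_state_means_na": dict(self.cpa_state_means_na),
            "clock_skew_s": self.clock_skew_s,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class Session:
    """A simulated multimodal session in physical units."""

    lfp: dict                 # label -> TimeSeries (V)
    accel: tuple              # (x, y, z) TimeSeries (g)
    ecg: TimeSeries           # V
    cpa: TimeSeries           # nA
    video_intensity: TimeSeries
    truth: GroundTruthLog
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# generation helpers

def _default_schedule(rng: np.random.Generator, duration_s: float) -> list:
    """Wake/NREM/REM cycle with realistic rodent bout lengths."""
    bouts = []
    t = 0.0
    while t < duration_s:
        for state, lo, hi in ((WAKE, 100, 300), (NREM, 120, 300), (REM, 60, 120)):
            dur = float(rng.uniform(lo, hi))
            bouts.append((state, dur))
            t += dur
            if t >= duration_s:
                break
    return bouts


def _states_per_second(schedule, duration_s: float) -> tuple:
    """Per-second state labels and (start, end, state) bouts clipped to the
    session."""
    secs = int(np.ceil(duration_s))
    states = np.empty(secs, dtype=object)
    bouts = []
    t = 0.0
    for state, dur in schedule:
        if t >= duration_s:
            break
        end = min(t + dur, duration_s)
        states[int(t):int(np.ceil(end))] = state
        bouts.append((t, end, state))
        t = end
    if t < duration_s:   # schedule shorter than the session: pad with NREM
        states[int(t):] = NREM
        bouts.append((t, duration_s, NREM))
    return states, bouts


def _unit_band_noise(rng, n, fs, lo, hi):
    """Band-limited Gaussian noise normalised to unit standard deviation."""
    hi = min(hi, fs / 2 * 0.98)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _raised_cosine_box(n_rise, n_flat, n_fall):
    """0 -> 1 raised-cosine rise, flat top, raised-cosine fall."""
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / max(n_rise, 1)))
    fall = 0.5 * (1 + np.cos(np.pi * np.arange(n_fall) / max(n_fall, 1)))
    return np.concatenate([rise, np.ones(n_flat), fall])


def _sd_waveform(n_tail: int, fs: float, amplitude_v: float,
                 duration_s: float) -> np.ndarray:
    """SD excursion sampled from its onset: raised-cosine fall over
    ``_SD_FALL_S``, plateau to ``duration_s``, exponential recovery."""
    u = np.arange(n_tail) / fs
    w = np.zeros(n_tail)
    fall = u < _SD_FALL_S
    w[fall] = -amplitude_v / 2 * (1 - np.cos(np.pi * u[fall] / _SD_FALL_S))
    plateau = (u >= _SD_FALL_S) & (u < duration_s)
    w[plateau] = -amplitude_v
    rec = u >= duration_s
    w[rec] = -amplitude_v * np.exp(-(u[rec] - duration_s) / _SD_RECOVERY_TAU_S)
    return w


def _movement_envelope(rng, states_1s, seizures, duration_s) -> np.ndarray:
    """Per-second movement amplitude in g."""
    secs = len(states_1s)
    m = np.zeros(secs)
    moving = False
    amp = 0.0
    for s in range(secs):
        state = states_1s[s]
        if state == WAKE:
            if moving:
                if rng.random() < _WAKE_P_STOP:
                    moving = False
            else:
                if rng.random() < _WAKE_P_START:
                    moving = True
                    amp = float(rng.uniform(*_WAKE_AMP_RANGE))
            m[s] = amp if moving else _WAKE_BASE_ACT
        elif state == REM:
            moving = False
            m[s] = _REM_TWITCH_AMP if rng.random() < _REM_TWITCH_P else 0.0
        else:
            moving = False
    for sz in seizures:
        m[int(sz.onset_s): int(np.ceil(sz.onset_s + sz.duration_s))] = \
            _SEIZURE_MOVEMENT_AMP
    return m


def simulate_session(cfg: ScenarioConfig) -> Session:
    """Generate one deterministic multimodal session plus its ground truth."""
    fs = float(round(cfg.fs_hz))
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    spf = int(fs)   # samples per second

    ss = np.random.SeedSequence(cfg.seed)
    ss_sov, ss_lfp, ss_acc, ss_ecg, ss_cpa, ss_video = ss.spawn(6)
    rng_sov = np.random.default_rng(ss_sov)

    schedule = cfg.sov_schedule or _default_schedule(rng_sov, cfg.duration_s)
    states_1s, bouts = _states_per_second(schedule, cfg.duration_s)

    def per_sample_mask(state):
        mask_1s = (states_1s == state).astype(np.float64)
        return np.repeat(mask_1s, spf)[:n]

    mask = {s: per_sample_mask(s) for s in (WAKE, NREM, REM)}

    # --- LFP channels -----------------------------------------------------
    lfp = {}
    lfp_streams = ss_lfp.spawn(len(cfg.channels))
    for ch, child in zip(cfg.channels, lfp_streams):
        rng = np.random.default_rng(child)
        delta = _unit_band_noise(rng, n, fs, 0.5, 4.0) * _NREM_DELTA_V
        theta = _REM_THETA_V * np.sin(
            2 * np.pi * _REM_THETA_HZ * t + rng.uniform(0, 2 * np.pi))
        floor = (_unit_band_noise(rng, n, fs, *_BROADBAND_BAND_HZ)
                 * _BROADBAND_FLOOR_V
                 + rng.standard_normal(n) * _WHITE_FLOOR_V)
        x = mask[NREM] * delta + mask[REM] * theta + floor

        for sz in cfg.seizures:
            i0 = int(round(sz.onset_s * fs))
            i1 = min(n, int(round((sz.onset_s + sz.duration_s) * fs)))
            seg_t = t[i0:i1] - sz.onset_s
            env = sps.windows.tukey(i1 - i0, alpha=0.1)
            x[i0:i1] += env * sz.amplitude_v * np.sin(
                2 * np.pi * sz.burst_freq_hz * seg_t)
            edge = min(int(2 * fs), (i1 - i0) // 2)
            x[i0:i1] -= sz.dc_shift_v * _raised_cosine_box(
                edge, (i1 - i0) - 2 * edge, edge)
            # sentinel spike: one large discharge at ictal onset
            k0 = max(0, i0 - int(0.05 * fs))
            spike_t = t[k0:i0 + int(0.05 * fs)] - sz.onset_s
            x[k0:i0 + int(0.05 * fs)] += 3 * sz.amplitude_v * np.exp(
                -(spike_t / 0.01) ** 2)

        for sd in cfg.sds:
            delay = sd.delays_for(cfg.channels).get(ch)
            if delay is None:
                continue
            i0 = int(round((sd.onset_s + delay) * fs))
            if i0 >= n:
                continue
            tail = _sd_waveform(n - i0, fs, sd.amplitude_v, sd.duration_s)
            x[i0:] += tail

        lfp[ch] = TimeSeries(x, fs_hz=fs, units="V", label=ch)

    # --- acceleration -----------------------------------------------------
    rng_acc = np.random.default_rng(ss_acc)
    m_1s = _movement_envelope(rng_acc, states_1s, cfg.seizures, cfg.duration_s)
    m = np.repeat(m_1s, spf)[:n]
    axes = []
    for axis in "xyz":
        carrier = _unit_band_noise(rng_acc, n, fs, 5.0, 30.0)
        values = m * carrier
        if axis == "z":
            values = values + 1.0   # gravity
        axes.append(TimeSeries(values, fs_hz=fs, units="g", label=f"acc_{axis}"))
    accel = tuple(axes)

    # --- ECG ----------------------------------------------------------------
    rng_ecg = np.random.default_rng(ss_ecg)
    arrhythmia = sorted(cfg.ecg.arrhythmia, key=lambda a: a[0])
    pending = list(arrhythmia)
    peak_times = []
    tt = 0.3
    while tt < cfg.duration_s - 0.1:
        peak_times.append(tt)
        rr = (1.0 / cfg.ecg.rate_hz) * (
            1.0 + cfg.ecg.rr_jitter * rng_ecg.uniform(-1, 1))
        if pending and tt >= pending[0][0]:
            rr = float(pending.pop(0)[1])
        tt += rr
    peak_idx = np.round(np.array(peak_times) * fs).astype(int)
    peak_idx = peak_idx[peak_idx < n]
    ecg_vals = np.zeros(n)
    half = int(0.02 * fs)
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = cfg.ecg.amplitude_v * np.exp(-(kernel_t / 0.003) ** 2)
    for idx in peak_idx:
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        ecg_vals[lo:hi] += kernel[half - (idx - lo): half + (hi - idx)]
    ecg_vals += rng_ecg.standard_normal(n) * cfg.ecg.noise_v
    ecg = TimeSeries(ecg_vals, fs_hz=fs, units="V", label="ECG")

    # --- CPA current --------------------------------------------------------
    rng_cpa = np.random.default_rng(ss_cpa)
    means_1s = np.array([cfg.cpa.state_mean_na.get(s, 0.0) for s in states_1s])
    mean_per_sample = np.repeat(means_1s, spf)[:n]
    innov = rng_cpa.standard_normal(n) * cfg.cpa.noise_na * np.sqrt(
        1 - cfg.cpa.ar_coef ** 2)
    ar = sps.lfilter([1.0], [1.0, -cfg.cpa.ar_coef], innov)
    cpa = TimeSeries(mean_per_sample + ar, fs_hz=fs, units="nA", label="CPA")

    # --- video intensity ----------------------------------------------------
    rng_video = np.random.default_rng(ss_video)
    fr = cfg.video.frame_rate_hz
    nf = int(round(cfg.duration_s * fr))
    frame_t = np.arange(nf) / fr
    # a lagging video clock shows movement that happened clock_skew_s earlier
    src_t = frame_t - cfg.clock_skew_s
    sec_idx = np.clip(np.floor(src_t).astype(int), 0, len(m_1s) - 1)
    m_frames = m_1s[sec_idx]
    intensity = (cfg.video.baseline
                 + cfg.video.gain * m_frames * rng_video.uniform(0, 1, nf)
                 + cfg.video.noise_sd * rng_video.standard_normal(nf))
    video = TimeSeries(intensity, fs_hz=fr, units="a.u.", label="video_mean")

    # --- ground truth -------------------------------------------------------
    sds_truth: dict = {ch: [] for ch in cfg.channels}
    for sd in cfg.sds:
        for ch, delay in sd.delays_for(cfg.channels).items():
            sds_truth[ch].append({
                "onset_s": sd.onset_s + delay,
                "offset_s": sd.onset_s + delay + sd.duration_s,
                "amplitude_v": sd.amplitude_v,
            })
    truth = GroundTruthLog(
        seizures=[(sz.onset_s, sz.onset_s + sz.duration_s)
                  for sz in cfg.seizures],
        sds=sds_truth,
        sov_epochs=bouts,
        r_peak_times_s=peak_idx / fs,
        cpa_state_means_na=dict(cfg.cpa.state_mean_na),
        clock_skew_s=cfg.clock_skew_s,
    )
    return Session(lfp=lfp, accel=accel, ecg=ecg, cpa=cpa,
                   video_intensity=video, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# export to the native binary dialect

@dataclass
class ExportResult:
    paths: list
    clipped_samples: int


def export_session(session: Session, header: sf.RecordingHeader,
                   out_dir) -> ExportResult:
    """Write a session as hourly ``.emu`` files.

    Physical units are inverted to raw codes through the stream-format
    scaling, so reading the files back and reconverting matches the
    original within half an LSB per sample.  Signals beyond full scale
    saturate; the clipped-sample count is reported.
    """
    fs = header.sample_rate_hz
    for ts in list(session.lfp.values()) + [session.ecg]:
        if ts.fs_hz != fs:
            raise ValueError("session sampling rate does not match the header")
    n = len(next(iter(session.lfp.values())).values)

    codes = np.zeros((n, sf.N_CHANNELS), dtype=np.int32)
    clipped = 0
    for i, label in enumerate(header.channel_labels):
        if label in session.lfp:
            volts = session.lfp[label].values
        elif label == session.ecg.label:
            volts = session.ecg.values
        else:
            continue
        gain = header.gain_for_channel(i)
        raw = np.rint(volts * gain / header.vref_volts * (1 << 23))
        clipped += int(np.sum((raw < -(1 << 23)) | (raw > (1 << 23) - 1)))
        codes[:, i] = np.clip(raw, -(1 << 23), (1 << 23) - 1).astype(np.int32)

    accel_codes = np.zeros((n, 3), dtype=np.int16)
    for j, axis_ts in enumerate(session.accel):
        raw = np.rint(axis_ts.values[:n] / header.accel_full_scale_g * (1 << 15))
        clipped += int(np.sum((raw < -(1 << 15)) | (raw > (1 << 15) - 1)))
        accel_codes[:, j] = np.clip(raw, -(1 << 15), (1 << 15) - 1).astype(np.int16)

    counters = np.arange(n, dtype=np.int64) % sf.COUNTER_MOD
    per_file = int(fs * 3600)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for k, start in enumerate(range(0, n, per_file)):
        stop = min(start + per_file, n)
        hdr = replace(header,
                      start_time_utc=header.start_time_utc + 3600.0 * k)
        path = os.path.join(out_dir, sf.hourly_filename(hdr.rig_id,
                                                        hdr.start_time_utc))
        with open(path, "wb") as fh:
            fh.write(sf.encode_header(hdr))
            fh.write(sf.encode_packet_array(
                counters[start:stop], codes[start:stop],
                accel_codes[start:stop]))
        paths.append(path)
    return ExportResult(paths=paths, clipped_samples=clipped)


# ---------------------------------------------------------------------------
# plain-text scenario configs

def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a scenario from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    kwargs: dict = {}
    for key in ("duration_s", "seed", "fs_hz", "clock_skew_s"):
        if key in d:
            kwargs[key] = d.pop(key)
    if "channels" in d:
        kwargs["channels"] = tuple(d.pop("channels"))
    if "sov_schedule" in d and d["sov_schedule"] is not None:
        kwargs["sov_schedule"] = tuple(
            (s, dur) for s, dur in d.pop("sov_schedule"))
    elif "sov_schedule" in d:
        d.pop("sov_schedule")
    if "seizures" in d:
        kwargs["seizures"] = tuple(SeizureSpec(**sz) for sz in d.pop("seizures"))
    if "sds" in d:
        kwargs["sds"] = tuple(
            SdSpec(**{**sd, "channel_delays_s": sd.get("channel_delays_s")})
            for sd in d.pop("sds"))
    for key, cls in (("ecg", EcgSpec), ("cpa", CpaSpec), ("video", VideoSpec)):
        if key in d:
            sub = dict(d.pop(key))
            if key == "ecg" and "arrhythmia" in sub:
                sub["arrhythmia"] = tuple(tuple(a) for a in sub["arrhythmia"])
            kwargs[key] = cls(**sub)
    if d:
        raise ValueError(f"unknown scenario fields: {sorted(d)}")
    return ScenarioConfig(**kwargs)
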
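# dcemu

A toolkit for the computational stack of a **DC-sensitive epilepsy monitoring
unit (EMU)** — the kind of rig used for chronic, synchronized multimodal
home-cage monitoring of rodent epilepsy models: 16-channel DC-coupled
LFP/ECoG, ECG, tri-axis head acceleration, constant-potential amperometry
(CPA) for tissue oxygen, and synchronized video.

It is written for experimenters and analysts who need to go from the rig's
raw hourly binary files (or from physical-unit traces) to counted seizures,
spreading-depolarization (SD) events, cardiac RR series, hypnograms, oxygen
calibrations, and a video/electrophysiology synchronization verdict — and
for anyone who wants a fully synthetic, ground-truthed test bench for such
detectors.

## What's inside

* **`stream_format`** — bit-exact reader/writer for the rig's hourly files:
  a 4096-byte self-describing header followed by 63-byte telemetry packets
  (3-byte counter, two opaque 3-byte AFE status words, 16 big-endian 24-bit
  channel codes, 3 little-endian 16-bit acceleration codes). Raw codes
  convert to physical units as `V = code · (vref/gain) / 2²³` (±4.5 V
  dynamic range at gain 1) and `g = code · FS / 2¹⁵`. A counter audit finds
  acquisition dropouts; trailing partial packets are warned about, never
  silently dropped.
* **`signal_conditioning`** — zero-phase 4th-order Butterworth filters with
  the pipeline's fixed conventions (0.5–125 Hz LFP band, 0.5 Hz near-DC
  low-pass, 2–125 Hz acceleration band), Welch PSD (2048-sample Hann
  windows, 50 % overlap), 1 s spectrograms, and windowed RMS acceleration
  power.
* **`event_detection`** — the detectors:
  * *SD*: on the 0.5 Hz low-passed DC-coupled trace, onset at a downward
    crossing of **7.5 mV** relative to the value **3 s** earlier; offset at
    the upward crossing of **2 mV** above the onset potential.
  * *Seizures*: 9–16 Hz band-power burst candidates with hysteresis,
    consolidated by the counting rule — events **> 10 s** long and spaced
    **≥ 10 min** apart (closer events merge into one).
  * *Cardiac*: R peaks from the 15–125 Hz band (adaptive threshold, 60 ms
    refractory); RR intervals as first differences of peak times.
  * *Vigilance*: WAKE from accelerometer activity, REM from a 4–7 Hz theta
    peak with low movement, NREM from maximal 0.5–4 Hz delta power.
* **`electrochem`** — floating-potentiostat current (`i = (V₁−V₂)/R`), the
  five DAC stimulus waveforms (CPA, FSCV, LTPV, DPV, sine + DC), oxygen
  calibration (middle-80 s point statistic, stoichiometric dilution, linear
  fit over 0.09–0.23 mM/L), and in vivo CPA post-processing (1 Hz low-pass,
  1 kHz → 20 Hz) with state-conditioned averaging.
* **`sync_check`** — dual actigraphy (video: mean |ΔI| per 1 s window;
  accelerometer: windowed RMS), 10 mHz high-pass, normalized
  cross-correlation; a synchronized rig peaks at lag 0 ± 1 s.
* **`synth`** — a seeded simulator that generates whole multimodal sessions
  (state-dependent LFP rhythms, seizures with ~5 mV DC shifts, ≥ 20 mV SD
  excursions with propagation delays, movement-coupled video, ECG, CPA)
  together with a ground-truth log for scoring every detector.
* **`cli`** — the `emu` command: `convert`, `detect-sd`, `detect-seizure`,
  `sov`, `rr`, `cpa-calibrate`, `waveform`, `sync-check`, `simulate`,
  `report`. Every run writes a manifest (config echo, version, input
  checksums).

## Worked example

```python
import numpy as np
from dcemu import (ScenarioConfig, SdSpec, simulate_session, detect_sd,
                   accel_actigraphy, video_actigraphy, sync_lag,
                   fit_o2_calibration)

cfg = ScenarioConfig(
    duration_s=600.0, seed=42,
    sds=(SdSpec(onset_s=200.0, amplitude_v=0.035, duration_s=45.0),
         SdSpec(onset_s=420.0, amplitude_v=0.025, duration_s=35.0)),
)
session = simulate_session(cfg)

for event in detect_sd(session.lfp["HPL"]):
    print(f"SD on {event.channel}: onset {event.onset_s:.1f} s, "
          f"trough {1e3 * event.min_potential_v:.1f} mV, "
          f"duration {event.duration_s:.1f} s")

lag, r = sync_lag(accel_actigraphy(session.accel),
                  video_actigraphy(session.video_intensity), max_lag_s=60.0)
print(f"video/accel sync: lag {lag:+.1f} s (peak correlation {r:.2f})")

conc = np.linspace(0.09, 0.23, 8)
cal = fit_o2_calibration(list(zip(conc, 100 * conc + 5)))
print(f"O2 calibration: {cal.slope_na_per_mm:.1f} nA per mM/L, r2 = {cal.r2:.3f}")
```

prints

```
SD on HPL: onset 201.8 s, trough -35.3 mV, duration 50.5 s
SD on HPL: onset 422.2 s, trough -25.2 mV, duration 38.8 s
video/accel sync: lag +0.0 s (peak correlation 0.92)
O2 calibration: 100.0 nA per mM/L, r2 = 1.000
```

Both planted SDs are recovered within ~2 s of their onsets (the detector
fires once the 3 s look-back drop crosses 7.5 mV, i.e. shortly *into* the
fall) with troughs at the planted depths; the zero-skew session's actigraphy
correlation peaks at lag 0; the noiseless calibration line is recovered
exactly.

The same flow from the shell:

```bash
emu simulate --scenario scenario.yaml --out session/
emu detect-sd session/*.emu --channel HPL --out sd_events.csv
emu sync-check session/*.emu session/video_intensity.csv
```

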
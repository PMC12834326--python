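# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `dcemu`, and what the synthetic test bench does and does
not establish about real recordings.

## Signals and the binary dialect

All signals travel as uniformly sampled `TimeSeries` in physical units
(volts, g, nanoamperes); sample *n* of a series sits at `t0_s + n/fs`.

The hourly-file dialect is fixed by the acquisition hardware: a 4096-byte
header, then 63-byte packets — 3-byte big-endian wrap-around counter, 3-byte
AFE-1 status, 8 × 3-byte big-endian two's-complement channel codes, 3-byte
AFE-2 status, 8 more channel codes, and 3 × 2-byte little-endian
acceleration codes. Channel codes use the front end's native big-endian
order and acceleration codes the accelerometer's native little-endian
order, so other readers can interoperate. The two status words are carried
opaquely; their flag bits belong to the converter datasheet and are not
interpreted. The header content is only constrained to "configuration
details in 4096 bytes", so the dialect here is self-describing UTF-8
`key=value` lines (magic string + format version first), zero-padded to
exactly 4096 bytes — inspectable with any pager and size-exact.

ADC scaling is `volts = code · (vref/gain)/2²³`, giving ±4.5 V at gain 1
and vref 4.5 V; acceleration is `g = code · full_scale/2¹⁵`. Inversion
rounds to nearest and saturates, so a physical-unit round trip is exact to
half an LSB per sample and clipping is counted, never silent. File rotation
is by elapsed samples (`fs · 3600` packets), not wall clock; a trailing
partial packet (power loss) surfaces as a warning with its byte count.
Acceleration samples are treated as per-packet (channel-rate) values; any
on-device decimation is outside the format's scope.

## Filtering and spectral conventions

The filter family is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero phase. Zero phase matters because every detector
reports event *times*; a causal filter would bias onsets late by its group
delay. Fixed band conventions: 0.5–125 Hz for LFP/ECoG display and
spectra, 0.5 Hz low-pass for near-DC analysis, 2–125 Hz for acceleration
(the 2 Hz edge removes static gravity), 15–125 Hz for cardiac traces. The
acceleration band's high edge clips automatically below Nyquist for
lower-rate sensors.

Average spectra use Welch's method, 2048-sample Hann windows at 50 %
overlap (the overlap/taper are the field defaults; stated so results are
reproducible). Spectrograms and windowed "RMS power" use consecutive
non-overlapping 1 s windows — the acceleration power per window is the RMS
of the band-filtered three-axis vector magnitude, which reads as
amplitude-in-g and pairs with the 1 s spectrogram columns.

## Spreading-depolarization detector

SDs are mass-depolarization waves producing large (tens of mV), slow
negative DC shifts lasting tens of seconds. The detector operates on the
0.5 Hz low-passed DC-coupled trace. Onset: the first sample where
`x(t) − x(t − 3 s) < −7.5 mV`, with the 3 s look-back implemented as an
exact sample shift `round(3·fs)`. Offset: the first subsequent upward
crossing of `onset potential + 2 mV`. The detector then re-arms. Events
whose offset is not reached by the end of the trace are emitted with the
offset at trace end and a `truncated` flag rather than dropped. The
detector is derivation-agnostic (referential or bipolar traces alike).

Two numerical details:

* Threshold comparisons carry a 1 µV absolute tolerance. After the
  zero-phase low-pass, a trace constructed to sit *exactly* on a threshold
  lands within ~1e-12 of it (filter coefficient rounding), making the
  comparison a float coin flip; 1 µV (0.05 % of the smaller threshold,
  far below electrode noise) makes the boundary deterministic without
  shifting it at any physiological scale.
* `amplitude_v` is defined as onset potential minus trough. Because the
  onset fires once the look-back drop reaches 7.5 mV, the onset potential
  already sits ≈ 7.5 mV below baseline, so this statistic under-reads the
  full excursion depth by construction. When scoring recovery of planted
  events the toolkit therefore compares the *trough* (`min_potential_v`,
  baseline-referenced) against the planted depth; that statistic recovers
  a 35 mV excursion within a few percent.

The interaction with seizures is a design constraint, not an accident:
seizure-associated DC shifts are ~5 mV, below the 7.5 mV onset criterion,
so seizures never masquerade as SDs at default parameters. Propagation
across channels is summarized by sorting per-channel onsets (ties broken by
label) with delays relative to the earliest.

## Seizure candidates and the counting rule

The electrographic signature — a sentinel spike, then a 9–16 Hz spike
burst, ending in a sharp power decrease — is only qualitatively specified,
so candidate generation is the simplest detector consistent with it:
per-channel 9–16 Hz band power on 1 s windows, a baseline equal to the
rolling 5 min median, a threshold of 5× baseline, and 2-window hysteresis
on both edges; overlapping per-channel intervals merge with the union of
their channel sets. All parameters are exposed. An optional sentinel-spike
gate exists conceptually but is not a criterion by default because the
spike has no quantitative definition.

Counting follows the rule: merge candidates spaced closer than 10 min into
one event (clusters are one episode), then keep events strictly longer than
10 s. Merge-then-filter was chosen over drop-the-later-event because
clustered seizure–SD pairs form grouped episodes; a consequence is that a
cluster of short candidates can become one long counted event.

## Cardiac R peaks and RR intervals

The cardiac trace is band-passed at 15–125 Hz; polarity is auto-detected
from the skewness of the filtered trace. Peaks are local maxima above an
adaptive threshold — half the 99.5th percentile of each 2 s block, floored
at 4 robust standard deviations — with a 60 ms refractory period
(supporting rat rates up to 1000 bpm). RR intervals are first differences
of peak times, so their sum telescopes exactly to last-minus-first peak
time. Movement/chest-muscle artifact rejection is out of scope; in
practice RR analysis is restricted to still periods.

## Vigilance scoring

Fixed 10 s epochs (the epoch length is a free choice; 10 s resolves rodent
bouts without starving the spectral estimate). Per epoch: WAKE if the
median 1 s acceleration power exceeds the wake threshold — 3× the
session's 20th-percentile acceleration power, floored at 0.02 g. The
relative term adapts to sensor gain; the absolute floor keeps degenerate
all-quiet or all-active sessions from producing a meaningless threshold
(REM twitches at ~0.004 g stay well below it, locomotion at ≥ 0.05 g well
above). Otherwise REM if the theta (4–7 Hz)/delta (0.5–4 Hz) band-power
ratio exceeds 1.5 *and* the spectral argmax over 0.5–12 Hz lies in theta;
otherwise NREM if the argmax lies in delta; otherwise UNSCORED. Epochs
tile the scored span contiguously.

## Electrochemistry

The floating potentiostat grounds the counter electrode, lets the
reference float, and drives the working electrode; current is the sense
resistor's potential difference over its resistance, positive when point 1
is above point 2. The function generator produces the five stimulus
waveforms; discontinuous ones (pulse trains, staircases) compute their
phase by integer-sample modulo whenever the period is commensurate with
the DAC update rate, so periodicity is bit-exact rather than
float-mod-jittery. The DPV convention here applies the pulse during the
final `pulse_s` of each staircase tread.

Oxygen calibration: each point is the mean of the centred 80 s of a ~5 min
CPA recording (mixing transients excluded); concentrations follow ideal
dilution `c = c_sat · v_air/(v_air + v_n2)` with the air-saturated default
0.23 mM/L (the arterial anchor of the physiological range, configurable —
its temperature dependence is the user's responsibility); the fit is
ordinary least squares restricted to 0.09–0.23 mM/L. In vivo CPA traces
are low-passed at 1 Hz and stride-decimated from 1 kHz to 20 Hz — the
anti-alias cutoff sits 10× below the output Nyquist, so a plain stride
after the low-pass is adequate and preserves the stated order of
operations. State-conditioned means average current over hypnogram bouts
that keep at least 60 s clear of any seizure or SD event.

## Synchronization check

Video actigraphy is the windowed mean of the absolute first time-derivative
of pixel intensity (per-pixel-then-average for full frames; the frame-mean
reduction is accepted directly). Accelerometer actigraphy is the windowed
RMS acceleration. Both sit on a 1 s grid, are high-passed at 10 mHz
(first-order Butterworth, forward–backward — adequate for a single slow
drift pole on a 1 Hz grid), mean-removed, and Pearson-correlated at every
integer lag within ±120 s; normalization makes the peak value a confidence
score. One-second windows bound lag resolution at ±1 window, hence the
0 ± 1 s acceptance for a synchronized rig. The overlap precondition
(≥ 10× the maximum lag) keeps per-lag correlations from degenerating.

## The simulator and what it shows

The simulator emulates the *phenomenology the detectors key on*, not
biophysics: NREM delta-band noise (150 µV), REM theta (200 µV at 6 Hz),
and a broadband 0.5–45 Hz floor (50 µV) common to all states — wake LFP is
low-voltage desynchronized, which also keeps 9–16 Hz band power
state-independent so vigilance transitions cannot mimic seizure onsets.
Seizures add a sentinel spike, a tapered 9–16 Hz burst (0.5 mV) and a
smooth 5 mV negative DC shift; SDs are raised-cosine falls over 6 s to
≥ 20 mV (a fall speed at which even the smallest physiologic amplitude
trips the 7.5 mV/3 s rule within 3 s of the planted onset), a plateau to
the configured 30–60 s duration, then exponential recovery (τ = 4 s), with
per-channel propagation delays. Movement is a per-second envelope:
continuous low-level wake activity (0.04 g — awake home-cage rats are
rarely perfectly still) with Markov locomotor bouts (start 0.3/s, stop
0.2/s, 0.05–0.3 g), sparse REM twitches (0.004 g), quiescent NREM, and
0.5 g convulsive bursts during seizures; three acceleration axes modulate
independent 5–30 Hz carriers, with gravity on z. ECG is a 360 bpm (±2 %
jitter) impulse train convolved with a 3 ms Gaussian QRS kernel; planted
arrhythmias insert known long RR intervals. CPA is a per-state mean (REM
52, NREM 50, WAKE 49 nA — REM above NREM, matching the oxygen-delivery
direction) plus AR(1) noise (0.2 nA, φ = 0.95). Video intensity couples
multiplicatively to the movement envelope; a planted clock skew shifts the
video stream's content in time.

All randomness flows from one master seed through per-modality spawned
substreams, so the same seed reproduces a session bit for bit and adding a
modality never perturbs the others. Every planted event lands in a
serializable ground-truth log.

What passing tests show: the detectors implement their stated rules
exactly (threshold boundaries, counting semantics, timing to the sample),
recover planted events under realistic amplitudes and clean backgrounds,
and the whole chain survives the binary format round trip. What they do
not show: performance under electrode drift, movement artifact in the DC
band, chewing/EMG contamination of ECG, non-stationary seizure
morphologies, or video illumination changes — none of which the generator
emulates. Detection thresholds on real data remain the experimenter's
responsibility.

## Problem sizes

Simulated sessions in the test and acceptance runs are 20 s–30 min at
1 kHz (format fixtures use lower rates): long enough for several vigilance
cycles, the 10× max-lag sync overlap, and stable rolling baselines, while
keeping the full suite around half a minute on one CPU. The acceptance
script uses a 30 min session for the synchronization lag and 0.1 mV /
0.5 s sweep grids for the threshold boundaries.

## Known limitations

* The SD detector assumes a DC-coupled input; it warns on exactly
  zero-mean traces but cannot verify coupling.
* Seizure candidate generation is deliberately minimal; morphologically
  quiet seizures (no 9–16 Hz burst) are invisible to it.
* CPA cannot decouple oxygen concentration from the diffusion
  coefficient; state-conditioned means inherit that ambiguity.
* EDF export is not provided; decoded channels export to CSV.
* The sync check resolves lag only to the 1 s actigraphy grid.
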
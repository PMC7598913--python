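# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic data do and do not emulate, and the design
decisions taken where more than one reasonable option existed.

## The virtual amplifier

**Structure.** An amplifier channel is an ordered cascade: a front
(instrumentation) stage with flat gain, followed by second-order sections,
each either high-pass or low-pass with corner frequency f₀, quality factor Q
and per-stage gain G. The default instrument is front 10× → two-pole
high-pass (0.28 Hz, Q = 0.71, 10×) → two-pole low-pass (200 Hz, Q = 0.71,
10×), nominal total gain 1000×. The stage list is fully configurable, so a
four-section variant (two high-pass + two low-pass) can be instantiated; the
default uses one section of each kind, the reading consistent with a
measured 10–90 % rise time near 1.9 ms (a doubled low-pass chain is slower:
the simulated two-LP variant exceeds the 1.4–2.4 ms bracket).

Q = 0.71 is used literally rather than as shorthand for 1/√2 ≈ 0.7071; the
difference is 0.4 % at the corner (|H(f₀)| = Q·G for a second-order section)
and visible only in tests that assert at the 10⁻³ level. Two-pole sections
roll off at 12 dB/octave asymptotically; a nameplate figure of 6 dB/octave
sometimes quoted for such filters describes a single pole and is not
reproduced by a true second-order model.

**Non-idealities.**

* *CMRR* is a single frequency-independent common→differential leak
  10^(−CMRR/20) applied at the input. Benches report one CMRR number at
  60 Hz, so a frequency-dependent model would be unconstrained.
* *Input impedance* enters as the resistive divider Zin/(Zin+Rs) applied to
  the differential source (`input_loading`); default Zin = 0.87 GΩ.
* *Noise* is white Gaussian added at the input and band-limited by the
  amplifier itself. The per-sample standard deviation is
  `noise_rms_uv·sqrt((fs/2)/ENBW)` where ENBW is the equivalent noise
  bandwidth of the normalized magnitude response (≈ 222 Hz for the default
  spec), so the gain-normalized output noise RMS equals `noise_rms_uv`
  (default 1.3 µV) regardless of fs. A seed is mandatory whenever noise is
  on; noisy simulations are otherwise refused rather than silently
  irreproducible.
* *Saturation* is hard clipping at ±rail_v (default ±3 V, the battery
  rails). The real op-amp headroom below the rails is unspecified; hard
  clipping at the rail is the simplest disclosed choice.

**Discretization.** Each section is converted separately by the bilinear
transform after prewarping its own corner (ω₀ → 2fs·tan(ω₀/2fs)), then the
sections run in cascade (`scipy.signal.sosfilt`). Prewarping pins each
corner exactly at any legal fs, which is what matters for a 1 kHz
acquisition of a 200 Hz low-pass. The bilinear frequency warp still
compresses the response elsewhere: with corners far below fs (the 100 kHz
bench condition) the magnitude error is < 0.1 % and phase error < 10⁻⁴ rad
across 0.01–1000 Hz, but at fs = 1 kHz the deviation grows to ~2 % by
125 Hz. Consequences: sampled-signal tests near Nyquist should use the
high-rate condition, and `simulate_channel` warns when fs < 4× the highest
low-pass corner. A corner at or above Nyquist is a validation error.

**Rise time** is measured on the simulated step output as the time between
the 10 % and 90 % crossings of the post-step maximum, each located by linear
interpolation between the straddling samples. The default spec at 100 kHz
gives 1.85 ms, inside the 1.4–2.4 ms bracket around typical hardware
measurements; an independent ODE-integration oracle validates the
single-section case to 1 %.

## Bench metrics

All windowed statistics tile the trace into non-overlapping windows
(remainder discarded) and report mean and SEM = sd/√n across windows.
Full-length protocol durations follow bench practice (5-min takes, 30-s RMS
windows, 20×15-s SNR windows, 20-window impedance runs); the default
desk-scale protocol shortens recordings to 60 s with proportionally
shortened windows so window counts are preserved, and the report notes which
mode produced it.

* **CMRR** is reported input-referred: 20·log₁₀((RMS_out/G)/RMS_in). With
  the default 115 dB spec the residual common-mode signal is below the
  modeled noise floor, so the protocol reads ≈ −108 dB (noise-limited) —
  the same saturation effect a physical bench shows. Parameter-recovery
  tests therefore use a 100 dB variant, where the estimator recovers the
  configured value within 1 dB.
* **SNR** uses a Hann periodogram per window: signal = fundamental bin ± 3
  bins; noise = total − DC region − signal − harmonics 2..6; capped at
  +150 dB (a noiseless sine is otherwise infinite; with a bin-centered tone
  the Hann leakage outside ±2 bins is exactly zero, so the cap is actually
  reached). Proprietary SNR routines differ in leakage treatment, so this
  documented method is fixed and cross-checked against an independent
  time-domain least-squares sine-fit oracle (agreement within 0.5 dB over
  20 seeds) rather than chasing bug-compatibility with any particular tool.
* **Phase discrepancy** Hilbert-transforms both narrowband traces, takes the
  per-sample analytic-signal phase difference, trims one cycle per edge, and
  reports circular mean ± SEM. Broadband references trigger a warning.
* **Effective gain** is the per-window RMS ratio. Windows must hold an
  integer number of cycles (the protocol uses 1-s windows at 5/10/25/50/100
  Hz) and the first half of each high-rate recording is discarded: the
  0.28 Hz high-pass section has a ~0.8 s time constant and its start-up
  transient would otherwise bias the first windows.
* **Input impedance** applies Zin = R·RMS_R/(RMS₀ − RMS_R) per paired
  window and summarizes as median [IQR]. A pair with RMS_R ≥ RMS₀ raises a
  named non-measurable error instead of returning a negative impedance.
* **ANOVA** is computed from sums of squares directly (F from the F
  distribution), with identical zero-variance groups defined as F = 0,
  p = 1; pairwise follow-ups are two-sample t tests with p multiplied by
  the number of comparisons and capped at 1. `scipy.stats.f_oneway` serves
  as the independent reference in tests, never as the implementation.

## Synthetic data

`synth_session` emulates what the engine must handle, not rodent biophysics:

* EEG = 1/f^α background (spectral shaping of white noise with a single
  full-length FFT, PSD floored below 0.5 Hz to avoid the DC pole; α = 1
  default, 80 µV RMS) + Gaussian-bump band oscillations (default one 6 Hz
  theta-like band, 30 µV) + a damped-sinusoid evoked template (default
  40 µV, 8 Hz, 300 ms, 80 ms decay) added at each event time.
* EMG = broadband noise (20–300 Hz) modulated by a slowly varying positive
  envelope (burst rate 0.5 Hz), 60 µV RMS.
* Events repeat periodically (default every 3 s, 1-s stimuli — the cadence
  of an LED synchronization benchmark: a 36-min schedule yields exactly 720
  onsets) and drive a TTL line; the truth record returns the exact event
  times and template.

Each component is rescaled to its exact target RMS after shaping, so spectra
and amplitudes are deterministic given the seed; generators are
byte-reproducible. What this does **not** show: passing tests say nothing
about non-stationary artifacts, electrode drift, movement noise, line
interference, or realistic ERP morphology — the generator's job is to make
round-trip, recovery and averaging properties exactly checkable.

The per-trial SNR used in ERP-recovery tests is a *power* ratio between the
template (over its support) and the background; at power SNR 0.1 and 200
trials the √N averaging gain predicts a template correlation ≈ 0.98, and the
tests require > 0.95. (Reading "SNR 0.1" as an amplitude ratio would make
the target correlation unreachable at 200 trials: the expected value is
≈ 0.82.)

## Engine conventions

* Time is in seconds; sample indices are 0-based. Each subject's session
  clock is zeroed at its own start; sample 0 is the first device sample at
  or after the start time, and the device clock stays in the metadata.
* Chunks default to the 10 Hz update cadence and must be contiguous per
  device; a gap raises an integrity error and marks the stream
  discontinuous.
* ERP windows default to 0.1 s pre + 0.9 s post (1-s total, event at t = 0,
  enough pre-stimulus context to see a preceding nosepoke at −0.1 s); both
  are configurable. The streaming accumulator retains a window-length tail
  across chunk boundaries, so streaming and batch accumulation are
  bit-identical (same events, same addition order).
* Onset detection thresholds at 1.5× the median with an optional refractory
  period (a deliberate addition for noise robustness; half the minimum
  expected off-time is the recommended setting). The threshold convention
  assumes a positive baseline, as a phototransistor or TTL buffer provides;
  test fixtures use a non-zero dark level for this reason.
* The recording format is little-endian float32 interleaved frames plus a
  JSON sidecar and an events CSV — inspectable and append-friendly. The
  simulated DAQ quantizes to float32 at the backend boundary, so
  generator → dispatch → writer → reader round trips are bit-exact with the
  amplifier bypassed. The layout is this package's own, not compatible with
  any other system's files. Only TTL digital event channels are
  implemented; multiplexed analog event encoding has no published scheme to
  follow.
* Video synchronization registers (DAQ time, frame index) pairs at the
  update cadence and recovers per-frame timestamps by piecewise-linear
  interpolation using the earliest registration of each frame; frames
  outside the registered range are not extrapolated. A constant camera
  latency is recovered to within half a frame period.

## Scaled defaults and problem sizes

Simulated sessions default to 60 s at 1 kHz with three analog + one digital
channel per subject; the 12-subject demonstrations and the acceptance
checks use that scale, and longer runs are a configuration change, not a
code path change. Bench protocols default to the 60-s desk scale described
above with `--full-length` restoring 5-min takes. The corner-recovery
property holds to 1 % for corner separations ≥ 40× (any EEG-style
band-pass); at separations near 10× the two sections interact enough to
shift the measured −3 dB points by a little over 1 %, which is a property of
cascaded second-order filters, not of the finder — the finder itself
bisects the analytic magnitude to a relative tolerance of 10⁻⁶.

## Known limitations

* No SPICE-level component modeling, temperature drift, or op-amp slew
  limits; the rails clip instantaneously.
* CMRR is frequency-independent by construction.
* The noise model is white at the input; real front ends add 1/f noise
  below a corner frequency.
* Comparison amplifier parameter files shipped under `specs/` are synthetic
  stand-ins for "a general-purpose AC preamp" and "a digital headstage"
  expressed in this package's analog model — convenient for exercising
  multi-amplifier comparisons, not characterizations of physical devices.
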
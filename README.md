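# opbox

A virtual multi-subject EEG/EMG acquisition stack for rodent
electrophysiology, built around three pieces:

1. **A virtual analog amplifier.** Low-cost rodent EEG rigs typically use a
   battery-powered differential front end: an instrumentation stage (10×)
   followed by second-order Sallen–Key active filters — here one two-pole
   high-pass (0.28 Hz, Q = 0.71, 10×) and one two-pole low-pass (200 Hz,
   Q = 0.71, 10×) — for a total gain of 1000× over the 0.3–200 Hz EEG band.
   The model includes the non-idealities that matter on a real bench: finite
   CMRR (a common→differential leak of 10^(−CMRR/20)), finite input impedance
   (a Zin/(Zin+Rs) divider), input-referred Gaussian noise band-limited by
   the amplifier itself, and hard clipping at the ±3 V battery rails. Each
   filter section has the transfer function

       H_hp(s) = G·s² / (s² + (ω₀/Q)s + ω₀²),   H_lp(s) = G·ω₀² / (s² + (ω₀/Q)s + ω₀²)

   and is discretized by the bilinear transform with per-section corner
   prewarping, so sampled simulations keep the −3 dB points exactly where
   the analog design puts them.

2. **The standard amplifier bench protocol.** Windowed-RMS noise floors under
   several source impedances, input-referred CMRR against an ideal common-mode
   sine, periodogram SNR of a 100 µV pp test sine (with a time-domain sine-fit
   oracle as an independent cross-check), channel crosstalk, high-sample-rate
   (100 kHz) phase/gain/step/impulse characterization, and an input-impedance
   sweep using the divider formula Zin = 10 MΩ · RMS₁₀MΩ/(RMS₀Ω − RMS₁₀MΩ),
   summarized as median [IQR]. Group comparisons use a one-way ANOVA computed
   from sums of squares plus Bonferroni-corrected pairwise t tests.

3. **A multi-subject streaming engine.** Two CSV spreadsheets route subjects →
   boxes → device channels; a simulated DAQ backend delivers contiguous
   chunks at a 10 Hz update cadence; the engine starts/stops subjects
   asynchronously on a shared hardware clock, slices chunks sample-exactly
   per subject, detects TTL event onsets (1.5× median threshold), accumulates
   1-s event-related potentials (streaming updates are bit-identical to batch
   computation), computes real-time 0–100 Hz log-power spectra, decodes x4
   quadrature encoders, interpolates video frame timestamps from
   (DAQ-time, frame-index) registrations, and writes each subject to a simple
   binary format (`.obx` float32 frames + JSON sidecar + events CSV).

Seeded generators provide every input: bench waveforms (sine, triangle,
unipolar rectangular, step, impulse, with a precision 1/1000 voltage
divider) and synthetic rodent sessions (1/f EEG background, band
oscillations, damped-sinusoid evoked responses at known event times,
envelope-modulated EMG, TTL markers).

## Worked example

Characterize the default amplifier and run a two-subject simulated session:

```
$ opbox bench-amp --protocol gain --protocol corners --protocol cmrr --seed 7 --out results
{
  "cmrr_db": { "mean": -108.03, "sem": 0.054, "n_windows": 10, ... },
  "peak_gain": 1000.0350370500349,
  "peak_gain_freq_hz": 3.153188979355595,
  "corner_low_hz": 0.27887338675008067,
  "corner_high_hz": 200.80795930767243
}
```

The measured passband gain is 1000× and the −3 dB corners sit at 0.279 and
200.8 Hz — the designed 0.28/200 Hz corners, each shifted ~0.5 % by the
interaction of the two sections. The CMRR protocol reads −108 dB rather than
the configured −115 dB because the residual common-mode signal at the input
(0.63 µV RMS) is below the amplifier's own 1.3 µV noise floor: the estimate
is noise-limited, exactly as it is on a physical bench.

```python
from opbox import SessionConfig, run_simulated_session, write_example_routing

subs, boxes = write_example_routing("routing", n_subjects=2)
cfg = SessionConfig(subjects_csv=str(subs), boxes_csv=str(boxes),
                    out_dir="out", seed=7, duration_s=60.0)
results = run_simulated_session(cfg)
for sid, r in sorted(results.items()):
    print(sid, r["n_events"], r["erp_trials"], r["erp_skipped"])
# rat01 20 20 0
# rat02 20 20 0
```

Each subject gets `out/<id>.obx` (+ `.json` sidecar, `_events.csv`), an ERP
mean CSV (1-s window, stimulus at t = 0), a first-hour mean power-spectrum
CSV, and `out/manifest.json` records the config, seed, version and SHA-256 of
every output — rerunning the same config and seed reproduces all files
byte-for-byte. Here both subjects received 20 tone events in 60 s (one every
3 s) and all 20 event windows entered the ERP average.

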
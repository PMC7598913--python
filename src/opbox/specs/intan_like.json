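{
  "label": "intan-like",
  "_comment": "Synthetic stand-in parameters for a digital headstage-style amplifier expressed in this package's analog model (0.3-200 Hz band); for comparison runs only, not a characterization of any physical device.",
  "front_gain": 10.0,
  "stages": [
    {"kind": "high-pass", "corner_hz": 0.3, "q_factor": 0.71, "stage_gain": 10.0},
    {"kind": "low-pass", "corner_hz": 200.0, "q_factor": 0.71, "stage_gain": 10.0}
  ],
  "cmrr_db": 82.0,
  "input_impedance_ohm": 1800000000.0,
  "noise_rms_uv": 2.6,
  "rail_v": 1.2
}
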
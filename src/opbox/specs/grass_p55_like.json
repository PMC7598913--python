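{
  "label": "grass-p55-like",
  "_comment": "Synthetic stand-in parameters for a general-purpose AC preamplifier at 1000x gain, 0.3-300 Hz; for comparison runs only, not a characterization of any physical device.",
  "front_gain": 10.0,
  "stages": [
    {"kind": "high-pass", "corner_hz": 0.3, "q_factor": 0.71, "stage_gain": 10.0},
    {"kind": "low-pass", "corner_hz": 300.0, "q_factor": 0.71, "stage_gain": 10.0}
  ],
  "cmrr_db": 80.0,
  "input_impedance_ohm": 100000000.0,
  "noise_rms_uv": 0.55,
  "rail_v": 5.0
}
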
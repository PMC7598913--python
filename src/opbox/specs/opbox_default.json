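{
  "label": "opbox-default",
  "front_gain": 10.0,
  "stages": [
    {"kind": "high-pass", "corner_hz": 0.28, "q_factor": 0.71, "stage_gain": 10.0},
    {"kind": "low-pass", "corner_hz": 200.0, "q_factor": 0.71, "stage_gain": 10.0}
  ],
  "cmrr_db": 115.0,
  "input_impedance_ohm": 870000000.0,
  "noise_rms_uv": 1.3,
  "rail_v": 3.0
}
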
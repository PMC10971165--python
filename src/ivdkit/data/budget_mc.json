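{
  "description": "Relative uncertainty components (k=1, percent) of the Monte Carlo dose-ratio simulations.",
  "components": [
    {"name": "(s_w,air . p . W_air)_Co-60 from TRS-398", "kind": "B", "value": 0.8},
    {"name": "Clinic Monte Carlo physics", "kind": "B", "value": 1.6},
    {"name": "Phantom composition, density", "kind": "B", "value": 0.6},
    {"name": "Materials' cross-sections", "kind": "B", "value": 0.1}
  ]
}
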
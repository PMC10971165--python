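{
  "description": "Relative uncertainty components (k=1, percent) of the Farmer-chamber ionization measurements in the PMMA mini-phantom.",
  "components": [
    {"name": "N_D,w,Co-60 calibration factor", "kind": "B", "value": 0.6},
    {"name": "Electrometer calibration", "kind": "B", "value": 0.1},
    {"name": "Clinic Farmer reproducibility", "kind": "A", "value": 0.5},
    {"name": "ks . kpol . kP,T", "kind": "B", "value": 0.2},
    {"name": "Source positioning inside needles", "kind": "B", "value": 1.6},
    {"name": "Mechanical drilling of needle holes", "kind": "B", "value": 1.0}
  ]
}
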
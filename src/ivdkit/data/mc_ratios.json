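{
  "description": "Monte Carlo absorbed-dose ratios between the TG-43 full-scatter water sphere and the 10 cm x 10 cm PMMA mini-phantom for an Ir-192 HDR source, with k=1 relative uncertainties in percent.",
  "dpol_full_over_dpol_pmma": {"value": 1.075, "u_rel_pct": 2.4},
  "dw_full_over_dw_pmma": {"value": 1.096, "u_rel_pct": 2.4},
  "dair_full_over_dair_pmma": {"value": 1.086, "u_rel_pct": 2.4},
  "dw_full_over_dair_pmma": {
    "value": 1.226536,
    "u_rel_pct": 2.4,
    "derived": true,
    "note": "Back-derived as F x 1.112: the absolute (Dw,full / Dair,PMMA) ratio is not published directly, only the full-scatter factor F = 1.103 and the Co-60 denominator 1.112."
  },
  "experimental_validation": {
    "dpol_full_over_dpol_pmma": {"value": 1.084, "u_rel_pct": 2.1},
    "dair_full_over_dair_pmma": {"value": 1.106, "u_rel_pct": 2.9}
  }
}
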
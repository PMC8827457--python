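{
  "hadlock1984": {
    "description": "Polynomial regressions of gestational age (weeks) on head biometry (cm), after Hadlock et al. 1984; validity limited to the published measurement ranges.",
    "bpd": {
      "unit_in": "cm",
      "coefficients": [9.54, 1.482, 0.1676],
      "powers": [0, 1, 2],
      "valid_range_mm": [14.0, 105.0]
    },
    "hc": {
      "unit_in": "cm",
      "coefficients": [8.96, 0.54, 0.0003],
      "powers": [0, 1, 3],
      "valid_range_mm": [50.0, 360.0]
    }
  },
  "identity_stub": {
    "description": "Pass-through stub: GA in days equals the measurement value in mm; used for plumbing tests.",
    "bpd": {
      "unit_in": "raw",
      "coefficients": [0.14285714285714285],
      "powers": [1],
      "valid_range_mm": [0.0, 1000000.0]
    },
    "hc": {
      "unit_in": "raw",
      "coefficients": [0.14285714285714285],
      "powers": [1],
      "valid_range_mm": [0.0, 1000000.0]
    }
  }
}
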
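{
  "E": -3.64,
  "Grect": null,
  "Oinf": [
    3.76,
    0.4
  ],
  "Rinf": [
    0.74,
    0.52,
    1.0
  ],
  "combine_O": "product",
  "combine_R": "product",
  "conductance_mode": "absolute",
  "g": 62.0,
  "name": "MM-intm",
  "schema_version": "1.0",
  "tauO_I": [
    1.7,
    1.49,
    0.035
  ],
  "tauO_V": [
    0.29,
    48.56,
    738.24
  ],
  "tauR_I": [
    0.17,
    0.0081,
    -2.8,
    14.69,
    1.05,
    0.42
  ],
  "tauR_V": [
    24.77,
    80.92,
    164.75
  ]
}
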
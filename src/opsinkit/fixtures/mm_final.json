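{
  "E": -3.62,
  "Grect": null,
  "Oinf": [
    3.67,
    0.39
  ],
  "Rinf": [
    0.4,
    0.54,
    0.9987
  ],
  "combine_O": "product",
  "combine_R": "product",
  "conductance_mode": "absolute",
  "g": 62.22,
  "name": "MM-final",
  "schema_version": "1.0",
  "tauO_I": [
    3.7,
    3.35,
    0.037
  ],
  "tauO_V": [
    0.2,
    49.99,
    718.6
  ],
  "tauR_I": [
    0.18,
    0.0082,
    -3.0,
    15.57,
    0.998,
    0.429
  ],
  "tauR_V": [
    24.42,
    80.87,
    172.82
  ]
}
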
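{
  "E": 0.0,
  "Grect": [
    10.77,
    1.25,
    44.52
  ],
  "Oinf": [
    3.38,
    0.62
  ],
  "Rinf": [
    1.96,
    0.12,
    0.77
  ],
  "combine_O": "reciprocal_sum",
  "combine_R": "reciprocal_sum",
  "conductance_mode": "density",
  "g": 1.0,
  "name": "RSRS-final",
  "schema_version": "1.0",
  "tauO_I": [
    1.81,
    1.17,
    0.021
  ],
  "tauO_V": [
    23.14,
    -0.39,
    13.19
  ],
  "tauR_I": [
    10.0,
    0.56,
    -1.58,
    0.87,
    1.96,
    0.11
  ],
  "tauR_V": [
    99.74,
    -38.69,
    12.02
  ]
}
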
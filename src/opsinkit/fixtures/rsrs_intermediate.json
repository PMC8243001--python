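{
  "E": 0.0,
  "Grect": [
    9.91,
    1.24,
    46.17
  ],
  "Oinf": [
    3.45,
    0.71
  ],
  "Rinf": [
    2.03,
    0.13,
    0.71
  ],
  "combine_O": "reciprocal_sum",
  "combine_R": "reciprocal_sum",
  "conductance_mode": "density",
  "g": 1.0,
  "name": "RSRS-intm",
  "schema_version": "1.0",
  "tauO_I": [
    1.93,
    0.68,
    0.022
  ],
  "tauO_V": [
    23.26,
    0.14,
    12.4
  ],
  "tauR_I": [
    10.0,
    0.56,
    -1.59,
    0.88,
    1.96,
    0.11
  ],
  "tauR_V": [
    100.0,
    -38.94,
    14.7
  ]
}
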
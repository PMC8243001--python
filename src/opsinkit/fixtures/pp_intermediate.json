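{
  "E": 0.0,
  "Grect": [
    8.93,
    1.27,
    42.37
  ],
  "Oinf": [
    3.45,
    0.71
  ],
  "Rinf": [
    1.99,
    0.15,
    0.73
  ],
  "combine_O": "product",
  "combine_R": "product",
  "conductance_mode": "density",
  "g": 1.0,
  "name": "PP-intm",
  "schema_version": "1.0",
  "tauO_I": [
    1.99,
    0.67,
    0.034
  ],
  "tauO_V": [
    0.64,
    -89.16,
    14.31
  ],
  "tauR_I": [
    6.74,
    0.5,
    2.0,
    0.11,
    -1.3,
    0.88
  ],
  "tauR_V": [
    1.5,
    -70.01,
    19.13
  ]
}
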
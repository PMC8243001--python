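{
  "E": 0.0,
  "Grect": [
    9.1,
    1.27,
    41.47
  ],
  "Oinf": [
    3.44,
    0.68
  ],
  "Rinf": [
    2.25,
    0.065,
    0.75
  ],
  "combine_O": "product",
  "combine_R": "product",
  "conductance_mode": "density",
  "g": 1.0,
  "name": "PP-final",
  "schema_version": "1.0",
  "tauO_I": [
    1.93,
    0.88,
    0.03
  ],
  "tauO_V": [
    0.63,
    -88.67,
    8.37
  ],
  "tauR_I": [
    6.73,
    0.5,
    1.98,
    0.11,
    -1.28,
    0.88
  ],
  "tauR_V": [
    1.66,
    -64.54,
    28.55
  ]
}
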
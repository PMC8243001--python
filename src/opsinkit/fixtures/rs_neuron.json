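{
  "cm_uF_cm2": 1.0,
  "description": "Single-compartment regular-spiking cortical pyramidal cell: leak, transient Na, delayed-rectifier K and slow non-inactivating (M-type) K conductances with Traub-style kinetics shifted by a spike threshold parameter VT and an M-current time scale tau_max.",
  "e_k_mV": -90.0,
  "e_leak_mV": -70.3,
  "e_na_mV": 50.0,
  "g_kd_mS_cm2": 6.0,
  "g_leak_mS_cm2": 0.0205,
  "g_m_mS_cm2": 0.075,
  "g_na_mS_cm2": 56.0,
  "name": "regular-spiking cortical neuron",
  "schema_version": "1.0",
  "tau_max_ms": 608.0,
  "vt_mV": -56.2
}
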
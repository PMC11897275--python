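{
  "name": "synthetic_victim_high_fm",
  "description": "Synthetic exemplar victim (illustrative parameter set, not a literature drug model)",
  "compound": {
    "molecular_weight": 400.0,
    "log_d": 2.0,
    "pka_values": [],
    "aqueous_solubility": 10.0,
    "solubility_ref_ph": 6.5,
    "particle_radius": 25.0,
    "precipitation_time": 900.0,
    "peff": 3.0,
    "rbp": 1.0,
    "fup": 0.1
  },
  "disposition": {"vc": 1.0, "k12": 0.0, "k21": 0.0},
  "clearance": {
    "cl_cyp3a4_hepatic": 0.095,
    "vmax_mode": "linear",
    "cl_other_hepatic": 0.005,
    "cl_renal": 0.0,
    "fm_cyp3a4": 0.95,
    "fg": 0.5
  }
}
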
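{
  "name": "rifampicin",
  "compound": {
    "molecular_weight": 822.96,
    "log_d": 1.3,
    "pka_values": [[7.9, "base"], [1.7, "acid"]],
    "aqueous_solubility": 1.1,
    "solubility_ref_ph": 6.5,
    "particle_radius": 25.0,
    "precipitation_time": 900.0,
    "peff": 1.0,
    "rbp": 0.52,
    "fup": 0.16
  },
  "disposition": {
    "vc": 0.15145,
    "k12": 1.4219,
    "k21": 1.7949
  },
  "clearance": {
    "cl_cyp3a4_hepatic": 0.0179,
    "km": 0.028,
    "vmax_mode": "linear",
    "cl_other_hepatic": 0.0623,
    "cl_renal": 0.0169,
    "fm_cyp3a4": null,
    "fg": 1.0
  },
  "induction": {
    "ec50": 0.8,
    "emax": 14.6,
    "kdeg_liver": 0.019,
    "kdeg_gut": 0.030
  }
}
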
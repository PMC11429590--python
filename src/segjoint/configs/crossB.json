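{
  "cross_id": "B",
  "model": "MX2-A-AD",
  "params": {
    "m": 103.92,
    "d_a": 30.72,
    "d_b": -9.61,
    "poly_d": 15.95,
    "poly_h": 3.2,
    "sigma2_e": 67.07,
    "sigma2_pg": {"F2": 0.0, "BC1P1": 33.91, "BC1P2": 73.31}
  },
  "n_per_generation": {"P1": 50, "P2": 50, "F1": 48, "F2": 245, "BC1P1": 119, "BC1P2": 111}
}
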
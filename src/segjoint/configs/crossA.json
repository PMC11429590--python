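{
  "cross_id": "A",
  "model": "MX2-A-AD",
  "params": {
    "m": 107.11,
    "d_a": 22.43,
    "d_b": -6.34,
    "poly_d": 19.65,
    "poly_h": -0.52,
    "sigma2_e": 71.93,
    "sigma2_pg": {"F2": 0.0, "BC1P1": 239.25, "BC1P2": 26.25}
  },
  "n_per_generation": {"P1": 50, "P2": 50, "F1": 46, "F2": 217, "BC1P1": 128, "BC1P2": 123}
}
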
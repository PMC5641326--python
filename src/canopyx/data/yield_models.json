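{
  "aerial": {
    "response": "grain_yield_t_ha",
    "intercept": -19.02,
    "coefficients": {"WBI": 17.32, "SAVI": 6.49},
    "r2": 0.778,
    "sep": 0.555,
    "variance_shares": {"WBI": 0.402, "SAVI": 0.376}
  },
  "ground": {
    "response": "grain_yield_t_ha",
    "intercept": 1.41,
    "coefficients": {"GGA_gr": 6.46},
    "r2": 0.716,
    "sep": 0.625,
    "variance_shares": {"GGA_gr": 0.716}
  },
  "all": {
    "response": "grain_yield_t_ha",
    "intercept": -21.90,
    "coefficients": {"WBI": 15.83, "Hue_gr": 0.17, "GGA_gr": -7.39, "RDVI": 0.51, "T_mor": -0.48},
    "r2": 0.827,
    "sep": 0.499,
    "variance_shares": {"WBI": 0.210, "Hue_gr": 0.197, "GGA_gr": 0.192, "RDVI": 0.181, "T_mor": 0.047}
  }
}
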
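{
  "N2": {
    "n_alternatives": 2,
    "parameters": ["kappa", "beta", "I1", "I2", "xi"],
    "exact": [4, 1, 0.9, 1.1, 0.25],
    "calibrated": [4.01, 0.97, 0.894, 1.095, 0.24998],
    "standard_error": [0.10, 0.10, 0.026, 0.026, 0.00089],
    "z_score": [39.7, 9.7, 33.9, 41.4, 280.1]
  },
  "N3": {
    "n_alternatives": 3,
    "parameters": ["kappa", "beta", "I1", "I2", "I3", "xi"],
    "exact": [4, 1, 0.9, 1.1, 0.98, 0.25],
    "calibrated": [3.963, 0.998, 0.894, 1.094, 0.978, 0.24991],
    "standard_error": [0.088, 0.051, 0.023, 0.023, 0.023, 0.00073],
    "z_score": [45.0, 19.6, 38.8, 47.2, 42.9, 342.5]
  },
  "N10": {
    "n_alternatives": 10,
    "parameters": ["kappa", "beta", "I1", "I2", "I3", "I4", "I5", "I6", "I7", "I8", "I9", "I10", "xi"],
    "exact": [4, 1, 0.9, 1.1, 0.95, 1.2, 0.5, 0.75, 0.8, 1, 1, 1, 0.25],
    "calibrated": [4.08, 0.990, 0.898, 1.103, 0.954, 1.199, 0.484, 0.741, 0.796, 1.006, 1.008, 1.005, 0.25001],
    "standard_error": [0.17, 0.020, 0.056, 0.057, 0.056, 0.058, 0.062, 0.057, 0.056, 0.056, 0.056, 0.056, 0.00040],
    "z_score": [24.3, 48.9, 16.1, 19.4, 17.1, 20.6, 7.9, 13.0, 14.1, 17.9, 18.0, 17.9, 631.6]
  }
}
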
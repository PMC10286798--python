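{
  "description": "RI-normalized quartic polynomial for lettuce quantum use efficiency over blue/green/red/far-red irradiance fraction ratios. Coefficients are power-major: the four first-order fractions (B, G, R, FR), then squares, cubes and quartics in the same band order. The domain records the fraction ranges observed in the 20-treatment LED training set.",
  "terms": {"powers": [1, 2, 3, 4], "interactions": false},
  "intercept": -1.40e-4,
  "coefficients": [
    1.82e-4, 2.32e-4, -1.90e-4, 4.68e-4,
    2.06e-4, -4.20e-4, 1.03e-3, -5.25e-3,
    -7.71e-4, 1.53e-3, -1.10e-3, 2.92e-2,
    8.38e-4, -1.56e-3, 4.13e-4, -4.77e-2
  ],
  "normalize": "ri",
  "i_ref_w_m2": 32.8,
  "domain": {
    "blue": [0.0, 0.421],
    "green": [0.0, 0.605],
    "red": [0.254, 1.0],
    "far_red": [0.0, 0.321]
  }
}
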
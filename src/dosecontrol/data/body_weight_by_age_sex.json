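{
  "description": "Mean body weight (kg) by age bin and sex, used to impute missing body weights from age and sex. Piecewise constant over [lo, hi) age bins.",
  "provenance": "Approximate adult population means transcribed from US NHANES anthropometric reference tables (McDowell et al., Advance Data 2005); rounded to 0.1 kg. Ages outside the table are clamped to the nearest bin.",
  "bins": [
    {"lo": 18, "hi": 20, "M": 77.2, "F": 65.4},
    {"lo": 20, "hi": 30, "M": 83.4, "F": 71.1},
    {"lo": 30, "hi": 40, "M": 86.1, "F": 74.1},
    {"lo": 40, "hi": 50, "M": 87.4, "F": 76.7},
    {"lo": 50, "hi": 60, "M": 88.8, "F": 77.1},
    {"lo": 60, "hi": 70, "M": 88.8, "F": 76.6},
    {"lo": 70, "hi": 80, "M": 84.3, "F": 71.6},
    {"lo": 80, "hi": 120, "M": 78.2, "F": 64.6}
  ]
}
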
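{
  "name": "consistency",
  "terms": [
    {"variable": "li", "weight": 0.446, "reported_or": 1.562},
    {"variable": "homogeneous_enhancement", "weight": -1.02, "reported_or": 0.361}
  ],
  "threshold": 0.003,
  "positive_class": "soft",
  "negative_class": "hard"
}
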
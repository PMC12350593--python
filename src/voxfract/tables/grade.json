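{
  "name": "grade",
  "terms": [
    {"variable": "fd", "weight": 0.312, "reported_or": 0.732},
    {"variable": "age", "weight": -0.009, "reported_or": 0.991},
    {"variable": "homogeneous_enhancement", "weight": -1.645, "reported_or": 0.193},
    {"variable": "tumor_volume", "weight": 0.004, "reported_or": 1.004}
  ],
  "threshold": -3.114,
  "positive_class": "WHO grade 2",
  "negative_class": "WHO grade 1"
}
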
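{
  "table3": {
    "LV_10": {
      "B_s_10": {"weight": 0.6438, "std_weight": 0.991, "communality": 0.9819, "redundancy": 0.0},
      "Me_s_10": {"weight": 0.3723, "std_weight": 0.973, "communality": 0.9458, "redundancy": 0.0}
    },
    "LV_overall": {
      "VD_10": {"weight": -0.0165, "std_weight": -0.522, "communality": 0.2729, "redundancy": 0.2679},
      "B_s_10": {"weight": 0.5436, "std_weight": 0.982, "communality": 0.9639, "redundancy": 0.9463},
      "Me_s_10": {"weight": 0.4298, "std_weight": 0.964, "communality": 0.9287, "redundancy": 0.9117},
      "A_s_1": {"weight": 0.1177, "std_weight": 0.176, "communality": 0.0308, "redundancy": 0.055},
      "Cp_f_1": {"weight": 0.774, "std_weight": -0.703, "communality": 0.4944, "redundancy": 0.0}
    },
    "LV_1": {
      "A_s_1": {"weight": -0.7146, "std_weight": 0.638, "communality": 0.4068, "redundancy": 0.0},
      "Cp_f_1": {"weight": 0.774, "std_weight": -0.703, "communality": 0.4944, "redundancy": 0.0}
    }
  },
  "table4": {
    "order": ["LV_10", "LV_overall", "LV_1", "LV_setback"],
    "matrix": [
      [1.000, 0.991, 0.182, 0.898],
      [0.991, 1.000, 0.309, 0.925],
      [0.182, 0.309, 1.000, 0.409],
      [0.898, 0.925, 0.409, 1.000]
    ]
  },
  "table5": {
    "gof": 0.7236,
    "LV_overall": {
      "r2": 0.9818,
      "intercept": 0.0,
      "paths": {"LV_10": 0.9908}
    },
    "LV_setback": {
      "r2": 0.8731,
      "intercept": 0.0,
      "paths": {"LV_10": -0.9914, "LV_overall": 1.9065, "LV_1": 0.0013}
    }
  }
}
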
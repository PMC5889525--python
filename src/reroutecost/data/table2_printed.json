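{
  "colorectal": {
    "horizon": 60,
    "conversion_rate_printed": 0.043,
    "cost_per_test": 420,
    "a": 9242,
    "b": -546,
    "c": 479,
    "d": -1734,
    "total_1yr": 7442,
    "C": 1128,
    "D": -1012,
    "total_5yr": 8812,
    "delta_surv": 0.359,
    "cost_per_survivor": 24546,
    "yls": 1.43,
    "cost_per_yls": 6162
  },
  "breast": {
    "horizon": 60,
    "conversion_rate_printed": 0.078,
    "cost_per_test": 158,
    "a": 1883,
    "b": -497,
    "c": 128,
    "d": -1546,
    "total_1yr": -32,
    "C": 712,
    "D": -628,
    "total_5yr": 1469,
    "delta_surv": 0.512,
    "cost_per_survivor": 2870,
    "yls": 1.54,
    "cost_per_yls": 954
  },
  "prostate": {
    "horizon": 60,
    "conversion_rate_printed": 0.153,
    "cost_per_test": 157,
    "a": 874,
    "b": -887,
    "c": -128,
    "d": -2565,
    "total_1yr": -2706,
    "C": 616,
    "D": -1582,
    "total_5yr": -979,
    "delta_surv": 0.408,
    "cost_per_survivor": -2399,
    "yls": 1.24,
    "cost_per_yls": -789
  },
  "lung": {
    "horizon": 36,
    "conversion_rate_printed": 0.186,
    "cost_per_test": 127,
    "a": 559,
    "b": -534,
    "c": 669,
    "d": -952,
    "total_1yr": -258,
    "C": 907,
    "D": -577,
    "total_5yr": 356,
    "delta_surv": 0.149,
    "cost_per_survivor": 2388,
    "yls": 0.59,
    "cost_per_yls": 603
  }
}
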
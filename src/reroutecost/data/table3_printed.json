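{
  "colorectal": {
    "rerouted": 1303,
    "non_converted": 29977,
    "total_1yr": 9696503,
    "total_5yr": 11481948,
    "survivors": 468,
    "yls_total": 1863
  },
  "breast": {
    "rerouted": 577,
    "non_converted": 7436,
    "total_1yr": -18260,
    "total_5yr": 847750,
    "survivors": 295,
    "yls_total": 889
  },
  "prostate": {
    "rerouted": 964,
    "non_converted": 6320,
    "total_1yr": -2608444,
    "total_5yr": -943434,
    "survivors": 393,
    "yls_total": 1195
  },
  "lung": {
    "rerouted": 1714,
    "non_converted": 9236,
    "total_1yr": -441712,
    "total_5yr": 609938,
    "survivors": 255,
    "yls_total": 1011
  }
}
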
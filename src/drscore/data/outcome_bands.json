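{
  "description": "Per-procedure remission-probability bands over the DRS total. Probabilities for the intermediate scores (0.35 at DRS 9 under IISG, 0.55 at DRS 11 under IIDSG) are the derivation cohort's empirical rates, not smoothed model outputs.",
  "observed_range": {"IISG": [7, 13], "IIDSG": [8, 14]},
  "bands": {
    "IISG": [
      {"scores": [7, 8], "probability": 1.0},
      {"scores": [9, 9], "probability": 0.35},
      {"scores": [10, 14], "probability": 0.0}
    ],
    "IIDSG": [
      {"scores": [7, 10], "probability": 1.0},
      {"scores": [11, 11], "probability": 0.55},
      {"scores": [12, 14], "probability": 0.0}
    ]
  }
}
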
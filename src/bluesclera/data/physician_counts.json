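{
  "description": "Blue-sclera grading vs iron-deficiency status in a 67-patient suspected-ID inpatient cohort: 2x2 counts (index positive/negative x ID/NID) for each of three physician raters (grade >= 3 means blue) and for the two-of-three consensus rule.",
  "n_patients": 67,
  "n_id": 51,
  "n_nid": 16,
  "tables": {
    "r1": {"tp": 31, "fp": 5, "fn": 20, "tn": 11},
    "r2": {"tp": 23, "fp": 3, "fn": 28, "tn": 13},
    "r3": {"tp": 15, "fp": 1, "fn": 36, "tn": 15},
    "consensus": {"tp": 26, "fp": 1, "fn": 25, "tn": 15}
  }
}
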
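{
  "_comment": "Empirical seed-variant ranking rules. position_tiers: lower tier = better predicted on-target retention for a single seed mismatch at that guide position (positions 5-6 tolerated, 2 and 7 disruptive). retention_class_order: within a position, opposition classes created at the parent's target sites ranked by residual silencing retained (G:U wobble most tolerated). detox_class_order: same classes ranked by off-target discrimination (purine:purine mismatches discriminate best, so they detoxify best).",
  "position_tiers": {
    "5": 0,
    "6": 0,
    "3": 1,
    "4": 1,
    "8": 1,
    "2": 2,
    "7": 2
  },
  "default_position_tier": 1,
  "retention_class_order": [
    "gu_wobble",
    "pyr_pyr",
    "pur_pyr_mismatch",
    "pur_pur"
  ],
  "detox_class_order": [
    "pur_pur",
    "pur_pyr_mismatch",
    "pyr_pyr",
    "gu_wobble"
  ]
}
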
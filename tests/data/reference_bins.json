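{
  "double_ratio_max": {
    "edges": ["0.00019", "0.0015", "0.0071", "0.35"],
    "labels": ["Low", "Moderately low", "Moderate", "Moderately high", "High"],
    "direction_note": "higher = more double-positive cells"
  },
  "embedding_distance": {
    "edges": ["3.67", "4.02", "4.34", "4.77"],
    "labels": ["Very similar", "Somewhat similar", "Similar", "Dissimilar", "Very dissimilar"],
    "direction_note": "distance: low value = very similar genes"
  },
  "pearson_r": {
    "edges": ["-0.020", "-0.004", "0.004", "0.020"],
    "labels": ["Strongly negative correlation", "Weakly negative correlation", "Uncorrelated", "Weakly positive correlation", "Strongly positive correlation"],
    "direction_note": "sign gives direction of co-expression"
  },
  "safety_score": {
    "edges": ["-0.0071", "-0.000073", "0.0012", "0.013"],
    "labels": ["Unsafe", "Moderately low safety", "Safe", "Moderately high safety", "High safety"],
    "direction_note": "higher = safer"
  },
  "single_ratio_max": {
    "edges": ["0.11", "0.24", "0.45", "0.67"],
    "labels": ["Low", "Moderately low", "Moderate", "Moderately high", "High"],
    "direction_note": "higher = more active single target"
  }
}
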
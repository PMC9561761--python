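{
  "cutoff": 0.4014822983158088,
  "horizon_months": 12.0,
  "metadata": {
    "cv_deviance": 9.145495058790798,
    "lambda": 0.0698317712299489,
    "n_candidates": 6,
    "n_events": 20,
    "n_folds": 4,
    "n_samples": 24,
    "seed": 7,
    "selection": "min"
  },
  "pairs": [
    {
      "coefficient": 0.8029645966316176,
      "gene_a": "G0001",
      "gene_b": "G0008"
    }
  ],
  "tie_rule": "gt_zero_ties"
}
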
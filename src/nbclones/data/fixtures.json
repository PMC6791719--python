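{
  "version": 1,
  "description": "Printed clone-cohort summary statistics from the Flybow lineage-tracing experiment in pox(n)>pros(RNAi) neuroblast tumors, plus the best-fit free parameters.",
  "two_cell": {"p_cc": 0.29, "p_cs": 0.07, "p_ss": 0.64, "n_clones": 122},
  "singletons": {"p_qc": 0.02, "p_qs": 0.26, "n_clones": 338},
  "mean_ci_clone_size": {"value": 3.4, "time_days": 2.0, "n_clones": 75},
  "design": {
    "times_days": [0.3333333333333333, 2.0, 4.0, 8.0],
    "counts": [306, 299, 270, 338],
    "category_counts": {
      "CI": [117, 75, 13, 17],
      "MIXED": [8, 28, 57, 66],
      "SYP": [181, 196, 200, 255]
    }
  },
  "best_fit": {"p_ccc": 0.64, "ts_days": 1.3, "tc_days": 1.6},
  "printed_reduction": {"pc": 0.45, "p_ccs": 0.15, "p_css": 0.21, "qc": 0.04, "qs": 0.47}
}
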
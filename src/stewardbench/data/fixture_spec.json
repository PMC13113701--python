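{
  "version": "fixture-spec-1",
  "n_admissions": 493,
  "tables": {
    "primary_any_violation": {"n00": 393, "n01": 16, "n10": 76, "n11": 8},
    "carb_violation": {"n00": 448, "n01": 6, "n10": 36, "n11": 3},
    "aps_violation": {"n00": 461, "n01": 1, "n10": 30, "n11": 1},
    "mrsa_violation": {"n00": 444, "n01": 13, "n10": 32, "n11": 4},
    "broad_spectrum_any": {"n00": 155, "n01": 49, "n10": 143, "n11": 146},
    "coverage_micro_evaluable": {"n00": 38, "n01": 23, "n10": 10, "n11": 87}
  },
  "arm_totals": {
    "primary_any_violation": {"clin": 84, "llm": 24},
    "carb_violation": {"clin": 39, "llm": 9},
    "aps_violation": {"clin": 31, "llm": 2},
    "mrsa_violation": {"clin": 36, "llm": 17},
    "broad_spectrum_any": {"clin": 289, "llm": 195}
  },
  "delta_penalty": {
    "n_neg": 79,
    "n_pos": 16,
    "n_zero": 398,
    "sum": -108,
    "sum_sq": 330,
    "mean_rounded": -0.219,
    "sd_rounded": 0.789
  },
  "concordance": {
    "n_identical_set": 57,
    "n_same_primary_agent": 137,
    "n_any_overlap": 148,
    "n_no_overlap": 345
  },
  "subsets": {
    "continued_72h": 323,
    "micro_evaluable": 158,
    "non_evaluable": 335
  },
  "no_antibiotic": {"count": 5, "all_proxies_false": true}
}
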
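{
  "rates": {
    "stage1": {
      "stroke": {"mean": 2.9, "ci_low": 2.6, "ci_high": 3.2},
      "mi": {"mean": 1.3, "ci_low": 1.1, "ci_high": 1.5},
      "death": {"mean": 4.1, "ci_low": 3.7, "ci_high": 4.5},
      "mi_after_stroke": {"mean": 0.03, "ci_low": 0.01, "ci_high": 0.1},
      "recurrent_stroke": {"mean": 31.1, "ci_low": 22.5, "ci_high": 42.9},
      "death_after_stroke": {"mean": 0.3, "ci_low": 0.2, "ci_high": 0.5},
      "stroke_after_mi": {"mean": 0.02, "ci_low": 0.01, "ci_high": 0.08},
      "recurrent_mi": {"mean": 36.4, "ci_low": 23.7, "ci_high": 55.8},
      "death_after_mi": {"mean": 0.2, "ci_low": 0.1, "ci_high": 0.3}
    },
    "stage2": {
      "stroke": {"mean": 8.1, "ci_low": 7.7, "ci_high": 8.5},
      "mi": {"mean": 2.3, "ci_low": 2.1, "ci_high": 2.5},
      "death": {"mean": 8.9, "ci_low": 8.2, "ci_high": 9.1},
      "mi_after_stroke": {"mean": 0.13, "ci_low": 0.08, "ci_high": 0.2},
      "recurrent_stroke": {"mean": 55.1, "ci_low": 49.1, "ci_high": 61.9},
      "death_after_stroke": {"mean": 1.4, "ci_low": 1.2, "ci_high": 1.6},
      "stroke_after_mi": {"mean": 0.09, "ci_low": 0.06, "ci_high": 0.2},
      "recurrent_mi": {"mean": 44.9, "ci_low": 36.2, "ci_high": 55.7},
      "death_after_mi": {"mean": 0.4, "ci_low": 0.3, "ci_high": 0.5}
    }
  },
  "progression": {"mean": 0.2408, "ci_low": 0.2172, "ci_high": 0.2552},
  "relative_risks": {
    "stage1": {
      "stroke": {"mean": 0.85, "ci_low": 0.68, "ci_high": 1.06},
      "recurrent_stroke": {"mean": 0.68, "ci_low": 0.56, "ci_high": 0.84},
      "mi": {"mean": 0.98, "ci_low": 0.88, "ci_high": 1.09},
      "recurrent_mi": {"mean": 0.73, "ci_low": 0.64, "ci_high": 0.82},
      "death": {"mean": 0.98, "ci_low": 0.9, "ci_high": 1.06},
      "progression": {"mean": 0.61, "ci_low": 0.53, "ci_high": 0.7}
    },
    "stage2": {
      "stroke": {"mean": 0.86, "ci_low": 0.72, "ci_high": 1.01},
      "recurrent_stroke": {"mean": 0.74, "ci_low": 0.67, "ci_high": 0.81},
      "mi": {"mean": 0.86, "ci_low": 0.76, "ci_high": 0.96},
      "recurrent_mi": {"mean": 0.68, "ci_low": 0.58, "ci_high": 0.8},
      "death": {"mean": 0.87, "ci_low": 0.75, "ci_high": 1.0},
      "progression": null
    }
  },
  "costs": {
    "screening": {"mean": 28.71, "rel_range": 0.25},
    "drug": {"mean": 88.92, "rel_range": 0.25},
    "productivity": {"mean": 275.38, "rel_range": 0.25},
    "stroke_first_year": {"mean": 3249.55, "rel_range": 0.25},
    "stroke_subsequent": {"mean": 1525.64, "rel_range": 0.25},
    "mi_first_year": {"mean": 4710.83, "rel_range": 0.25},
    "mi_subsequent": {"mean": 428.26, "rel_range": 0.25}
  },
  "productivity_reduction_drug": 0.048,
  "productivity_window_years": 10,
  "utilities": {
    "hypertension": {"mean": 0.9, "ci_low": 0.79, "ci_high": 0.95},
    "stroke": {"mean": 0.63, "ci_low": 0.26, "ci_high": 0.88},
    "post_stroke": {"mean": 0.65, "ci_low": 0.46, "ci_high": 0.82},
    "mi": {"mean": 0.76, "ci_low": 0.5, "ci_high": 0.89},
    "post_mi": {"mean": 0.88, "ci_low": 0.67, "ci_high": 0.94}
  },
  "discount_rate": {"mean": 0.05, "ci_low": 0.0, "ci_high": 0.08},
  "wtp_per_gdp": 10438.66
}
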
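{
  "n_total": 1000,
  "seed": 42,
  "superiority_delta": 0.1,
  "followup_horizon": 120,
  "arm_a": {
    "lts_fraction": 0.5,
    "lts": {
      "family": "weibull",
      "anchor": {"time": 36, "survival": 0.5},
      "shape": 1.5,
      "survivor_fraction": 0.3
    },
    "sts": {
      "family": "weibull",
      "anchor": {"time": 12, "survival": 0.2},
      "shape": 2.0,
      "survivor_fraction": 0.1
    }
  },
  "arm_b": {
    "lts_fraction": 0.5,
    "lts": {
      "family": "weibull",
      "anchor": {"time": 36, "survival": 0.5},
      "shape": 1.5,
      "survivor_fraction": 0.3
    },
    "sts": {
      "family": "weibull",
      "anchor": {"time": 12, "survival": 0.2},
      "shape": 2.0,
      "survivor_fraction": 0.1
    }
  },
  "nominal_biomarker": {
    "enriched_arm": "A",
    "p1": 0.8,
    "p2": 0.6,
    "prevalence": 0.4
  },
  "numeric_biomarker": {
    "marking": {
      "enriched_arm": "A",
      "p1": 0.9,
      "p2": 0.7,
      "prevalence": 0.5
    },
    "mu_biomarker": 10.0,
    "sigma_biomarker": 2.0,
    "mu_non_biomarker": 5.0,
    "sigma_non_biomarker": 2.0
  },
  "attributes": [
    {"name": "age", "family": "normal", "params": {"mean": 62, "sd": 10}},
    {"name": "sex", "family": "uniform_nominal", "params": {"categories": ["female", "male"]}},
    {"name": "centre", "family": "uniform_nominal", "params": {"categories": ["c1", "c2", "c3"]}},
    {"name": "crp", "family": "exponential", "params": {"rate": 0.2}}
  ],
  "include_truth": false,
  "output": "cohort.csv"
}
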
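{
  "config": {
    "include_hrca": true,
    "parameters": [
      "age",
      "albumin",
      "b2m",
      "calcium",
      "egfr",
      "hemoglobin"
    ],
    "pvalue_mode": "neg_log10_minmax",
    "rank_endpoint": "os",
    "tree_max_depth": 4,
    "tree_min_leaf": 5
  },
  "cutoffs": {
    "age": {
      "direction": "high_if_gt",
      "threshold": 69.0
    },
    "albumin": {
      "direction": "high_if_le",
      "threshold": 3.5
    },
    "b2m": {
      "direction": "high_if_ge",
      "threshold": 5.5
    },
    "calcium": {
      "direction": "high_if_ge",
      "threshold": 10.52
    },
    "egfr": {
      "direction": "high_if_le",
      "threshold": 48.3
    },
    "hemoglobin": {
      "direction": "high_if_le",
      "threshold": 9.59
    }
  },
  "format": "crss-stage-model",
  "provenance": "synthetic:mmrf_like:seed=7",
  "rules": {
    "classes": [
      1,
      2,
      3
    ],
    "depth": 4,
    "feature_names": [
      "age",
      "albumin",
      "b2m",
      "calcium",
      "egfr",
      "hemoglobin",
      "hrca"
    ],
    "rules": [
      {
        "conditions": [
          {
            "feature": "age",
            "op": "<=",
            "threshold": 68.94034957885742
          },
          {
            "feature": "hemoglobin",
            "op": "<=",
            "threshold": 9.468799591064453
          }
        ],
        "n_train": 36,
        "probs": [
          0.0,
          1.0,
          0.0
        ],
        "stage": 2
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": "<=",
            "threshold": 68.94034957885742
          },
          {
            "feature": "hemoglobin",
            "op": ">",
            "threshold": 9.468799591064453
          },
          {
            "feature": "calcium",
            "op": "<=",
            "threshold": 10.589349746704102
          },
          {
            "feature": "b2m",
            "op": "<=",
            "threshold": 5.482899904251099
          }
        ],
        "n_train": 135,
        "probs": [
          1.0,
          0.0,
          0.0
        ],
        "stage": 1
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": "<=",
            "threshold": 68.94034957885742
          },
          {
            "feature": "hemoglobin",
            "op": ">",
            "threshold": 9.468799591064453
          },
          {
            "feature": "calcium",
            "op": "<=",
            "threshold": 10.589349746704102
          },
          {
            "feature": "b2m",
            "op": ">",
            "threshold": 5.482899904251099
          }
        ],
        "n_train": 5,
        "probs": [
          0.2,
          0.8,
          0.0
        ],
        "stage": 2
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": "<=",
            "threshold": 68.94034957885742
          },
          {
            "feature": "hemoglobin",
            "op": ">",
            "threshold": 9.468799591064453
          },
          {
            "feature": "calcium",
            "op": ">",
            "threshold": 10.589349746704102
          }
        ],
        "n_train": 16,
        "probs": [
          0.0,
          1.0,
          0.0
        ],
        "stage": 2
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": ">",
            "threshold": 68.94034957885742
          },
          {
            "feature": "calcium",
            "op": "<=",
            "threshold": 10.521549701690674
          }
        ],
        "n_train": 49,
        "probs": [
          0.0,
          1.0,
          0.0
        ],
        "stage": 2
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": ">",
            "threshold": 68.94034957885742
          },
          {
            "feature": "calcium",
            "op": ">",
            "threshold": 10.521549701690674
          },
          {
            "feature": "albumin",
            "op": "<=",
            "threshold": 3.516650080680847
          },
          {
            "feature": "b2m",
            "op": "<=",
            "threshold": 5.515000104904175
          }
        ],
        "n_train": 5,
        "probs": [
          0.0,
          0.8,
          0.2
        ],
        "stage": 2
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": ">",
            "threshold": 68.94034957885742
          },
          {
            "feature": "calcium",
            "op": ">",
            "threshold": 10.521549701690674
          },
          {
            "feature": "albumin",
            "op": "<=",
            "threshold": 3.516650080680847
          },
          {
            "feature": "b2m",
            "op": ">",
            "threshold": 5.515000104904175
          }
        ],
        "n_train": 135,
        "probs": [
          0.0,
          0.0,
          1.0
        ],
        "stage": 3
      },
      {
        "conditions": [
          {
            "feature": "age",
            "op": ">",
            "threshold": 68.94034957885742
          },
          {
            "feature": "calcium",
            "op": ">",
            "threshold": 10.521549701690674
          },
          {
            "feature": "albumin",
            "op": ">",
            "threshold": 3.516650080680847
          }
        ],
        "n_train": 19,
        "probs": [
          0.0,
          1.0,
          0.0
        ],
        "stage": 2
      }
    ],
    "training_fidelity": 0.995
  },
  "seed": 7,
  "stage_counts": {
    "1": 136,
    "2": 128,
    "3": 136
  },
  "version": 1,
  "weights": {
    "hr": {
      "scheme": "univariate_hr_minmax",
      "weights": {
        "age": 0.2976282277679199,
        "albumin": 0.9432639370597224,
        "b2m": 0.8667211908517238,
        "calcium": 0.7842062976508563,
        "egfr": 1.0,
        "hemoglobin": 0.7195695218113549,
        "hrca": 0.0
      }
    },
    "pvalue": {
      "scheme": "pvalue_scaled",
      "weights": {
        "age": 0.2751070976893614,
        "albumin": 0.9827215423447945,
        "b2m": 0.8691503434557464,
        "calcium": 0.877825615788216,
        "egfr": 1.0,
        "hemoglobin": 0.7568561607832387,
        "hrca": 0.0
      }
    },
    "rank": {
      "scheme": "multivariate_rank",
      "weights": {
        "age": 1.0,
        "albumin": 2.0,
        "b2m": 7.0,
        "calcium": 5.0,
        "egfr": 4.0,
        "hemoglobin": 6.0,
        "hrca": 3.0
      }
    }
  }
}
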
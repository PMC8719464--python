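{
  "version": "1.0",
  "description": "Summary tables of a fully crossed six-reader, 51-case observer study of CAD-aided breast-mass diagnosis: per-reader AUCs, sensitivity/specificity/PPV/NPV, BI-RADS category changes, and mean diagnosis times, unaided vs aided by the model's probability of malignancy.",
  "readers": [1, 2, 3, 4, 5, 6],
  "reader_groups": {"1": "junior", "2": "junior", "3": "middle", "4": "middle", "5": "senior", "6": "senior"},
  "case_counts": {"malignant": 22, "benign": 29},
  "auc": {
    "unaided": [0.842, 0.783, 0.889, 0.852, 0.866, 0.869],
    "aided": [0.920, 0.892, 0.922, 0.890, 0.904, 0.847],
    "printed_average": {"unaided": 0.850, "aided": 0.896, "difference": 0.046},
    "reported_p_value": 0.0209
  },
  "rates": {
    "sensitivity": {
      "unaided": [0.545, 0.682, 0.773, 0.773, 0.819, 0.773],
      "aided": [0.682, 0.864, 0.773, 0.864, 0.901, 0.773]
    },
    "specificity": {
      "unaided": [0.931, 0.621, 0.793, 0.862, 0.793, 0.863],
      "aided": [0.931, 0.621, 0.897, 0.931, 0.689, 0.897]
    },
    "ppv": {
      "unaided": [0.857, 0.577, 0.739, 0.810, 0.750, 0.809],
      "aided": [0.882, 0.633, 0.850, 0.905, 0.689, 0.850]
    },
    "npv": {
      "unaided": [0.729, 0.720, 0.821, 0.833, 0.851, 0.833],
      "aided": [0.794, 0.857, 0.838, 0.900, 0.909, 0.838]
    },
    "reported_binary_p_value": 0.0253,
    "flags": {
      "reader5_aided_sensitivity": "printed 0.901 but no count of 22 positives rounds to it; the PPV/NPV row implies 20/22 = 0.909 true positives (probable printing error)"
    }
  },
  "birads_changes": {
    "increase": [14, 11, 11, 17, 22, 5],
    "decrease": [4, 15, 13, 5, 4, 7],
    "closer_to_biopsy": [10, 15, 13, 8, 14, 7],
    "not_matching": [8, 11, 11, 14, 12, 5]
  },
  "times": {
    "unaided_mean_s": [55.27, 80.59, 63.90, 45.10, 42.35, 56.96],
    "aided_mean_s": [55.51, 81.18, 64.24, 42.59, 37.35, 43.96],
    "printed_difference": [0.24, 0.59, 0.34, -2.51, -5.0, -13.0],
    "reported_p_values": [0.955, 0.912, 0.928, 0.378, 0.089, 0.001]
  }
}
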
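{
  "combined_pairs": [
    "G0014:G0032",
    "G0044:G0106",
    "G0055:G0123"
  ],
  "config_hash": "21969fc3c27b",
  "down_mirnas": [
    "mir-0000",
    "mir-0001",
    "mir-0003"
  ],
  "empirical_p": 0.0,
  "planted_combined": [
    "G0014:G0032",
    "G0044:G0106",
    "G0055:G0123"
  ],
  "seed": 0,
  "stage_counts": {
    "catalog": {
      "in": 39,
      "out": 39
    },
    "combined_screen": {
      "in": 39,
      "out": 3
    },
    "drug_association": {
      "in": 8,
      "out": 1
    },
    "expression_screen": {
      "in": 39,
      "out": 2
    },
    "mirna_network": {
      "in": 24,
      "out": 6
    },
    "mutation_screen": {
      "in": 39,
      "out": 2
    },
    "simulate": {
      "in": 0,
      "out": 39
    },
    "survival": {
      "in": 2,
      "out": 2
    }
  }
}
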
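{
  "schema_version": 1,
  "name": "bronchial-airway lung-cancer classifier (locked)",
  "intercept": 3.3173,
  "coefficients": {
    "Age": 0.0623,
    "GG": 0.545,
    "GS": 0.1661,
    "GPY": 3.0205,
    "CA1": -0.4406,
    "CA2": -0.3402,
    "CA4": 0.1725,
    "CA7": 0.567,
    "CA9": -0.316,
    "CA10": -0.3791
  },
  "clusters": {
    "CA1": ["BST1", "CD177.1", "CD177.2"],
    "CA2": ["ATP12A", "TSPAN2"],
    "CA4": ["GABBR1", "MCAM", "NOVA1", "SDC2"],
    "CA7": ["CDR1", "CGREF1", "CLND22", "NKX3-1"],
    "CA9": ["EPHX3", "LYPD2"],
    "CA10": ["MIA", "RNF150"]
  },
  "cfgc": {
    "GG": {
      "type": "threshold",
      "gene": "RPS4Y1",
      "cutpoint": 7.5,
      "positive_if": "below"
    },
    "GS": {
      "type": "logistic",
      "intercept": 40.8579,
      "coefficients": {
        "SLC7A11": -0.4462,
        "CLND10": -2.1298,
        "TKT": -1.8256
      }
    },
    "GPY": {
      "type": "logistic",
      "intercept": -5.1429,
      "coefficients": {
        "RUNX1T1": 2.1891,
        "AKR1C2": -0.9506
      }
    }
  },
  "threshold": 0.65,
  "reference_means": null
}
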
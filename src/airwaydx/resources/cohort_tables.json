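{
  "comment": "Printed cohort count tables used by the reproduce-tables command: training-cohort categorical counts (lung cancer vs benign columns) and test-cohort detection counts.",
  "training": {
    "n_cancer": 223,
    "n_benign": 76,
    "sex": {
      "rows": ["female", "male"],
      "cols": ["lung_cancer", "benign"],
      "counts": [[97, 26], [126, 50]]
    },
    "smoking_status": {
      "rows": ["current", "former"],
      "cols": ["lung_cancer", "benign"],
      "counts": [[101, 26], [122, 50]]
    },
    "mass_location": {
      "rows": ["central", "peripheral", "central_and_peripheral"],
      "cols": ["lung_cancer", "benign"],
      "counts": [[86, 16], [60, 30], [60, 18]]
    }
  },
  "test": {
    "n_total": 163,
    "n_cancer": 78,
    "n_benign": 85,
    "bronchoscopy_detected_cancers": 40,
    "nondiagnostic_cancers": 38,
    "classifier_detected_nondiagnostic_cancers": 34,
    "combined_detected_cancers": 74
  }
}
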
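{
 "bmi": {
  "clump_config": {
   "p1": 1.0,
   "p2": 1.0,
   "r2": 0.1,
   "window_kb": 10000
  },
  "clumped": 35,
  "harmonized": 69,
  "qc": {
   "absent_from_panel": 0,
   "input": 80,
   "kept": 69,
   "low_imputation": 4,
   "strand_ambiguous": 7
  },
  "variants_per_threshold": {
   "0.001": 34,
   "0.01": 35,
   "0.05": 35,
   "0.1": 35,
   "0.5": 35,
   "1": 35,
   "1e-05": 34,
   "5e-08": 34
  }
 },
 "insomnia": {
  "clump_config": {
   "p1": 1.0,
   "p2": 1.0,
   "r2": 0.1,
   "window_kb": 10000
  },
  "clumped": 33,
  "harmonized": 69,
  "qc": {
   "absent_from_panel": 0,
   "input": 80,
   "kept": 69,
   "low_imputation": 4,
   "strand_ambiguous": 7
  },
  "variants_per_threshold": {
   "0.001": 31,
   "0.01": 31,
   "0.05": 33,
   "0.1": 33,
   "0.5": 33,
   "1": 33,
   "1e-05": 30,
   "5e-08": 28
  }
 }
}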
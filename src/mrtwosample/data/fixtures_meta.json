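{
  "vitd_to_adhd": {
    "exposure_name": "25(OH)D",
    "outcome_name": "ADHD",
    "exposure_trait_type": "continuous",
    "outcome_trait_type": "binary",
    "n_exposure": 79366,
    "n_outcome": 53293,
    "outcome_cases": 19099,
    "outcome_controls": 34194,
    "variance_explained": 0.0284,
    "p_threshold": 5e-08,
    "notes": "Exposure effects are per unit natural-log 25(OH)D; outcome effects are odds ratios for ADHD (European-ancestry subset). rs209955 stands in for rs17216707; its eaf is a European reference-panel lookup, not the exposure GWAS frequency."
  },
  "adhd_to_vitd": {
    "exposure_name": "ADHD",
    "outcome_name": "25(OH)D",
    "exposure_trait_type": "binary",
    "outcome_trait_type": "continuous",
    "n_exposure": 53293,
    "exposure_cases": 19099,
    "exposure_controls": 34194,
    "n_outcome": 79366,
    "variance_explained": 0.216,
    "p_threshold": 5e-08,
    "notes": "Exposure effects are ADHD odds ratios (European-ancestry subset); outcome effects are per unit natural-log 25(OH)D. Five instruments are LD proxies for leads absent from the outcome study; their printed European p-values may exceed the discovery threshold, which was met by the leads in the full sample."
  }
}
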
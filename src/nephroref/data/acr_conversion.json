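{
  "_comment": [
    "Albuminuria conversion coefficients on the ln-ACR (mg/g) scale.",
    "pcr_to_acr: three-segment log-linear conversion with additive sex/",
    "diabetes/hypertension terms, transcribed from the published PCR->ACR",
    "conversion equation used for CKD screening and prognosis. VERIFY these",
    "numbers against the primary source before any clinical use; they are",
    "shipped here so the pipeline runs end to end and are editable in place.",
    "dipstick_to_acr: SYNTHETIC crude fallback (fixed per-category ln-ACR",
    "medians, no stratum adjustment). The published stratified dipstick",
    "coefficients were not available when this file was written; replace",
    "base_ln_acr and the stratum terms with transcribed values when you",
    "have the primary source."
  ],
  "pcr_to_acr": {
    "intercept": 5.3920,
    "slope_low": 0.3072,
    "slope_mid": 1.5793,
    "slope_high": 1.1266,
    "female": -0.0773,
    "diabetes": 0.0797,
    "hypertension": 0.1265
  },
  "dipstick_to_acr": {
    "method": "category_median_fallback (synthetic)",
    "base_ln_acr": {
      "neg": 2.0794,
      "trace": 3.2189,
      "1+": 4.3820,
      "2+": 5.7038,
      "3+": 6.8024
    },
    "female": 0.0,
    "diabetes": 0.0,
    "hypertension": 0.0
  }
}
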
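{
  "features": [
    "GLCM_Entrop_25HUgl",
    "GLCM_InfCo1_HHL_25HUgl",
    "GLCM_sumEnt_HLL_25HUgl"
  ],
  "coefficients": [0.109, 0.0557, -0.109],
  "intercept": 0.0,
  "penalty": null,
  "cv_folds": 10,
  "prefilter_threshold": 0.1,
  "metadata": {
    "description": "Published ovarian radiomic TLS model: three weighted GLCM features applied to standardized inputs; intercept not reported (scores are used for ranking/dichotomization only)."
  }
}
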
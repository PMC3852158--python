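{
  "notes": "SYNTHETIC stand-in coefficients. Each equation is log-linear: log10(mass_g) = intercept + sum_i slopes[i] * log10(length_i_mm). The published non-phylogenetically-corrected limb-length body-mass regressions (and the synapsid-wide skull->femur equation) are not redistributable here; these defaults were chosen to be allometrically plausible for small quadrupeds (stylopodial-length slopes near the 2.5-2.8 range typical of length-mass scaling) so that the pipeline runs end to end. Substitute the published coefficients for real analyses.",
  "equations": [
    {
      "id": "humerus_length_univariate_synthetic",
      "inputs": ["humerus"],
      "slopes": [2.75],
      "intercept": -0.73
    },
    {
      "id": "femur_length_univariate_synthetic",
      "inputs": ["femur"],
      "slopes": [2.60],
      "intercept": -1.60
    },
    {
      "id": "humerus_femur_multivariate_synthetic",
      "inputs": ["humerus", "femur"],
      "slopes": [1.40, 1.30],
      "intercept": -1.35
    }
  ],
  "skull_to_femur_synthetic": {
    "comment": "synapsid-wide skull->femur length proxy, log10(femur_mm) = intercept + slope * log10(skull_mm); synthetic stand-in values",
    "slope": 0.90,
    "intercept": 0.05
  }
}
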
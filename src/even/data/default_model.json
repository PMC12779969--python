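{
  "schema_version": "1",
  "class_labels": [
    "bad",
    "good"
  ],
  "feature_names": [
    "e_edge",
    "p_plus"
  ],
  "means": [
    [
      0.8770340887667671,
      0.6306701052941815
    ],
    [
      0.9730184715664425,
      0.03228529303277465
    ]
  ],
  "coefficients": [
    [
      5598.588919040471,
      171.6105214800221
    ],
    [
      6125.109165027763,
      128.6590137677805
    ]
  ],
  "priors": [
    0.5,
    0.5
  ],
  "feature_max": [
    0.5681509623406397,
    0.05445902255669528
  ],
  "shared_covariance": [
    [
      0.00016365749052006223,
      -0.00022852284253089652
    ],
    [
      -0.00022852284253089652,
      0.011130294009727423
    ]
  ],
  "metadata": {
    "training_data": "synthetic",
    "description": "Fitted on 40 good + 40 bad seeded synthetic blob phantoms (8x8 grid of 64px tiles, Gaussian-mask degradation model). Not trained on experimental data; retrain for quantitative work.",
    "n_good": 40,
    "n_bad": 40,
    "seed": 20260901,
    "cv": {
      "mean_accuracy": 1.0,
      "mean_sensitivity": 1.0,
      "mean_specificity": 1.0
    }
  }
}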
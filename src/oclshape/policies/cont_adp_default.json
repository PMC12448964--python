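{
  "theta_hi": 0.5775586561463986,
  "theta_lo": 0.7751836034934756,
  "mu_lo": 0.16996331193927347,
  "mu_hi": 0.4,
  "_provenance": {
    "seed": [
      2024,
      1
    ],
    "population": 12,
    "generations": 20,
    "eps_grid": [
      -1.5,
      -2.0
    ],
    "n_seeds": 3,
    "best_cost": 92.0
  }
}
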
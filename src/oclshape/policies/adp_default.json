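{
  "theta_inc": 0.5267330019744269,
  "mu": 0.15947439671024277,
  "_provenance": {
    "seed": 2024,
    "population": 16,
    "generations": 40,
    "eval_eps_grid": [
      -1.0,
      -1.5,
      -2.0
    ],
    "eval_seeds": 5,
    "budget": 800,
    "best_cost": 92.2
  }
}
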
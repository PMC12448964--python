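"""Designing the adaptive teacher by differential evolution.

The ADP thresholds (theta_inc, mu) are fit by DE/rand/1/bin against
simulated curricula spanning biases on both sides of the incremental
teacher's failure boundary, minimising mean completion time with a
did-not-finish penalty.  By default this demo runs a reduced search in
about a minute; `--full` reproduces the shipped policy
(src/oclshape/policies/adp_default.json, provenance recorded inside).
"""

import argparse

import numpy as np

from oclshape.evolve import EvolveConfig, de_optimize

parser = argparse.ArgumentParser()
parser.add_argument("--full", action="store_true",
                    help="run the full search used for the shipped policy")
args = parser.parse_args()

if args.full:
    cfg, seed = EvolveConfig(), 2024  # population 16, 40 generations
else:
    cfg, seed = EvolveConfig(population=8, generations=6,
                             eval_eps_grid=(-1.0, -2.0), eval_seeds=2), 2024

rng = np.random.default_rng(np.random.SeedSequence([seed]))
policy, history = de_optimize(cfg, rng)

print(f"generations: {len(history) - 1}, "
      f"cost {history[0]:.1f} -> {history[-1]:.1f} "
      "(mean interactions to completion, DNF penalised)")
print(f"evolved thresholds: theta_inc={policy.theta_inc:.3f}, mu={policy.mu:.3f}")
print()
print("A low theta_inc with a positive mu means: increment early, demand "
      "visible learning progress to stay, otherwise drop back — an "
      "alternating curriculum rather than a staircase.")
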
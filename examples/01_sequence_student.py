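"""Reinforcement propagates backwards along an action chain.

A tabular TD student practices a fixed 5-step sequence whose innate
per-step success odds are sigma(-1) ~ 0.27.  We record the first practice
block at which each step's action value q_i crosses 0.5: later steps are
reinforced first because the terminal reward is the only source of value.
"""

import numpy as np

from oclshape import StudentParams, StudentState, run_interaction

rng = np.random.default_rng(0)
params = StudentParams.constant_bias(5, eps=-1.0, alpha=0.1)
state = StudentState.naive(5)

first_crossing = [None] * 5
for t in range(1, 3001):
    run_interaction(state, params, k=5, n_attempts=10, rng=rng)
    for i in range(5):
        if first_crossing[i] is None and state.q[i] > 0.5:
            first_crossing[i] = t
    if all(first_crossing):
        break

print("step      :", *range(1, 6))
print("crossed at:", *first_crossing)
print("final q   :", np.round(state.q, 2))
print()
print("Each entry is the practice block (10 episodes each) at which that "
      "step's value first exceeded 0.5; the non-increasing order shows the "
      "backward reinforcement wave from the rewarded final step.")
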
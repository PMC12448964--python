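"""The incremental teacher fails abruptly once the innate bias is too low.

INC raises difficulty whenever the student's estimated success rate at the
current level exceeds tau, and never lowers it.  Each increment triggers a
transient wave of extinction; when the naive success rate sigma(eps) is too
small (~15%, i.e. eps below about -1.7), extinction outpaces reinforcement
and the curriculum stalls.  A few points of the sweep:
"""

import numpy as np

from oclshape import CurriculumSpec, IncTeacher, StudentParams, run_curriculum

spec = CurriculumSpec()  # N=10 levels, T=10 attempts, tau=0.85, budget 1500
for eps in (-1.2, -1.6, -1.8, -2.0):
    done, times = 0, []
    for s in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([2, s]))
        params = StudentParams.constant_bias(10, eps, alpha=0.1)
        res = run_curriculum(IncTeacher(), params, spec, rng, record_q=False)
        done += res.completed
        times.append(res.interactions_used)
    print(f"eps={eps:+.1f}: completed {done}/5 runs, "
          f"mean interactions {np.mean(times):.0f}")

print()
print("Completion falls off sharply around eps ~ -1.6 to -1.8: below the "
      "boundary the teacher keeps assigning a level the student unlearns "
      "on, and the interaction budget (1500) runs out.")
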
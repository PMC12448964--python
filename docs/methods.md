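# Methods

`oclshape` simulates outcome-based curriculum learning (OCL): a teacher
chooses the difficulty of a student's next practice block using nothing but
the transcript of past successes and failures. The package contains the
student model, the transcript estimator, the teacher algorithms, the
optimiser that designs the adaptive teacher, and a continuous-difficulty
extension. This note records the models, the parameters that matter, and
the design choices made where more than one reasonable construction exists.

## Student model

The sequence-learning student must execute `N` correct actions in order to
obtain a single terminal reward. At step `i` the correct action is taken
with probability `σ(q_i + ε_i)`, where `ε_i` is a fixed innate bias
(log-odds of choosing correctly before any learning; for `K` equiprobable
actions, `ε = −log(K−1)`) and `q_i` is a learned action value initialised
to zero. Only the correct action's value is stored; all incorrect actions
share an implicit value of zero, which makes `σ(q_i + ε_i)` the complete
per-step description.

Values are updated online with an n-step TD rule (default n = 1, i.e.
TD(0)) with student discount 1. For a correctly executed step `i`:

    G_i = R·[success and k − i < n] + V_{i+n},     q_i ← q_i + α(G_i − q_i)

where `V_j = q_j` while step `j` was still attempted in the episode and 0
past termination, `k` is the assigned level (reward is delivered at step
`k`), and `R` is the reward magnitude. The failed step and everything after
it update nothing. Because every attempted step is visited exactly once and
bootstrap targets lie strictly ahead, the online rule is equivalent to a
single post-episode pass using pre-episode values, which is how it is
implemented.

This rule produces both signature dynamics of shaping:

* **Reinforcement wave** — value propagates backwards from the rewarded
  step, so later steps cross any value threshold before earlier ones.
* **Extinction wave** — immediately after an increment from `k` to `k+1`
  (so `q_{k+1} = 0`), every episode that is correct through step `k`
  changes `q_k` by exactly `−α·q_k`: withheld reward actively unlearns the
  previous frontier, and the decay propagates backwards exactly like the
  reinforcement wave.

### The reward magnitude R

`R` sets the ceiling of the learned values: under repeated reinforcement
`q_k → R`, so the per-step success ceiling is `σ(R + ε)`. With a unit
reward the full `N = 10` task is unpassable at the default threshold
(`τ = 0.85` requires per-step success ≥ 0.984, i.e. `q + ε ≥ 4.1`), so `R`
is a free scale parameter of the model. The package default `R = 6` places
the incremental teacher's failure boundary at `ε ≈ −1.7` — the regime where
the naive per-step success rate is ~15%. Larger `R` pushes the boundary to
lower `ε` (≈ −1.85 at `R = 7–8`, ≈ −2.15 at `R = 10`) and softens the
collapse; `R = 6` also gives the sharpest, most consistent failure (0/20
completions at `ε = −2.2`). One consequence worth knowing: at
`ε ≤ −2` the asymptotic true full-task success rate under `R = 6` is
`σ(4)^10 ≈ 0.835`, slightly below `τ`, so completions in that regime occur
when the (noisy) EMA estimate crosses the threshold — consistent with the
termination rule being defined on the observable estimate.

## Transcript estimator

Teachers observe per-level EMA estimates `ŝ_k` with decay `β = 0.1`
(configurable), updated per episode: `ŝ ← (1−β)ŝ + βx`. Estimates start at
0 on first visit and persist across level changes, so a teacher that drops
back remembers the student's competence there. `Δŝ` is the change over one
interaction block (`T = 10` episodes by default). A first visit therefore
typically has `Δŝ ≥ 0`, biasing adaptive teachers toward staying on new
levels until evidence accumulates. Sliding-window or filter-based
estimators would behave similarly; the EMA is kept for its two-number
state.

## Teachers

All discrete teachers clamp levels to `[1, N]`, start at level 1, and the
curriculum terminates when the assigned level is `N` and `ŝ_N ≥ τ` (the
true success probability is also logged for honesty, but plays no role in
control). Ties break upward: `ŝ = τ` increments; `Δŝ = μ` stays.

* **INC** increments iff `ŝ ≥ τ`, never decrements.
* **RAND** assigns a uniform level each interaction.
* **ADP** applies, in order: `ŝ ≥ θ_inc` → increment; `Δŝ ≥ μ` → stay;
  else decrement. The shipped thresholds (`θ_inc = 0.527`, `μ = 0.159`)
  were found by differential evolution (below); notably the optimiser chose
  a *low* increment threshold with a *positive* progress requirement — an
  alternating curriculum, not a staircase with a safety net.
* **Learning-progress baselines** (`lp-online`, `lp-naive`, `lp-window`,
  `lp-sampling`) chase the steepest per-level score slope (recency-weighted
  difference, last difference, least-squares slope over the last 5 scores,
  or a random draw from the recent-slope buffer), ε-greedy with ε = 0.1 and
  random tie-breaks, with unvisited levels prioritised. These are
  best-effort re-implementations from the published descriptions and are
  considered experimental.

## POMCP teacher

The teacher's problem is a POMDP whose hidden state is `(q, ε, α)`. The
belief is a set of particles (default 1000) with `q = 0` known at start and
`ε ~ U(−3, 0)`, `α ~ U(0.01, 0.5)` priors, assuming a homogeneous bias
within each particle. Per observed episode, each particle's weight is
multiplied by its predicted outcome probability and its `q` is advanced by
simulating one step-trace consistent with the outcome (sampling the failure
step from its conditional distribution) — an unbiased, cheap alternative to
exact trace marginalisation. Systematic resampling with Gaussian jitter on
`(ε, α)` (scales 0.05, 0.01, clipped to the prior support) restores
diversity when the effective sample size falls below half the particle
count; if every particle assigns zero probability to an observation the
hidden parameters are re-drawn from the prior with a warning.

Planning is POMCP: each of `n_simulations` (default 500) iterations samples
a particle as the root world state, descends a tree over moves
{decrement, stay, increment} by UCB1 (`c = √2`), branches observation nodes
on the block's **success count** (T+1 branches rather than 2^T ordered
sequences — a deliberate aggregation for tractable branching; the particle
filter itself still consumes the ordered sequence), expands one node per
iteration with an INC-rule rollout to `max_depth = 30`, and backs up
returns discounted by `γ = 0.98`. The simulated world carries its own copy
of the EMA tracker so termination inside the search mirrors the real loop.
The root action with the most visits is played. Tests validate the search
against an exact expectimax enumeration on a two-level task; planning cost
grows quickly as `ε` decreases (success gets rarer along every simulated
path), and at `ε ≈ −3` it is not practical.

## Designing ADP by differential evolution

`DE/rand/1/bin` (population 16, 40 generations, F = 0.7, CR = 0.9) searches
`θ_inc ∈ (0.5, 0.99)`, `μ ∈ (−0.2, 0.2)` (optionally also `β`). The cost of
a candidate is the mean number of interactions to completion over
`ε ∈ {−1.0, −1.5, −2.0}` × 5 fixed seeds, with incomplete runs charged
twice the budget. Training evaluations use a budget of 800 interactions
(cheaper than the benchmark budget of 1500; policies transfer because
completions under the evolved policy take ~100–300 interactions). Since INC
is a special case of the tree (`θ_inc = τ`, `μ = −∞`), the optimum can only
match or beat it. The resulting policy is frozen in
`src/oclshape/policies/adp_default.json` (provenance recorded inside) and
reused everywhere without retuning.

## Continuous curricula

Difficulty is a real `d ∈ (0, D]` realised as a chain of `⌈d/Δ⌉`
micro-steps with per-micro-step bias `ε·Δ` (default `Δ = 0.25`, `D = 5`),
so the naive log success probability is roughly linear in `d`. The student
uses the same TD rule with an n-step return over micro-steps (default
K = 2). With `Δ = 1` and K = 1 the machinery reduces bit-exactly to the
discrete task — this is a regression test.

The continuous teacher picks one of nine actions: {decrement, stay,
increment} × {shrink, keep, grow the increment}. Shrink/grow divide or
multiply the running increment by `g = 2` within `[0.25, 2.0]`; the
experimenter supplies only an initial rough guess (default 1.0). The
decision tree uses four thresholds (two on `ŝ`, two on `Δŝ`) with a fixed
leaf structure: high `ŝ` → increment (grow too if `Δŝ` is large); positive
enough `Δŝ` → stay; otherwise decrement, also shrinking the increment when
competence has fallen low (the overshoot signature). The thresholds are fit
with the same DE machinery and frozen in
`src/oclshape/policies/cont_adp_default.json`.

## Synthetic data and what passing tests show

All inputs are synthetic by design — the point of the simulator is a
student whose ground truth is known. The generator reproduces the study
conditions (N = 10 levels, T = 10 attempts, τ = 0.85, α = 0.1, β = 0.1,
budget 1500, homogeneous innate bias by default, heterogeneous supported).
It does not model inter-episode forgetting, motivation or satiety effects,
day structure, or any sensory noise beyond the Bernoulli outcome itself, so
passing tests show that the *algorithms* behave as described under the
stated learning model, not that a particular animal will.

## Numerical and reproducibility choices

* Single seeded `numpy` generator threaded through every stochastic
  operation; benchmark sub-seeds derive from
  `SeedSequence([master, teacher, eps, repeat])`, so runs are
  order-insensitive and outputs bit-identical across re-runs.
* Logistic evaluated in a numerically stable branch form; particle
  log-weights clamped at exp(−690) before normalisation.
* Policy evaluation seeds derive from `(ε, seed index)` only, making DE
  costs pure functions of the candidate.
* Degenerate inputs are errors, not silent clamps: `K < 2` actions,
  out-of-range levels or difficulties, empty blocks, invalid prior bounds.
  The one deliberate clamp is the teacher move at the level boundaries,
  which is part of the task definition.

## Problem sizes used in the test suite

Tests scale simulations to what the checks need: the collapse sweep uses
the full 13 × 10-run grid; teacher comparisons use 10 seeds; the
particle-filter recovery uses 20 seeds × 50 interactions × 1000 particles;
planner-vs-expectimax uses a two-level, two-attempt task with 2500
simulations per decision; full-size POMCP curricula appear only in the
examples.

## Known limitations

* The TD variant, reward scale, POMCP internals and the continuous student
  are reasonable reconstructions where finer published detail was not
  available; conclusions that depend on the exact collapse location should
  treat `R` as the calibrated quantity it is.
* Learning-progress baselines follow the cited descriptions loosely and
  should not be read as faithful reference implementations.
* POMCP here re-plans from the current belief each interaction and does not
  reuse subtrees; it is a research-grade planner, not an optimised one.
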
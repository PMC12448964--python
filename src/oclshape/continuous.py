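"""Continuous curricula: finely discretised difficulty and a nine-action teacher.

Difficulty is a real number d in (0, D], realised as a chain of
``ceil(d / grid)`` micro-steps, each with innate bias ``eps * grid`` so the
naive log success probability scales with d (difficulty is an intensive
scale).  The student learns with an n-step TD rule over micro-steps.  The
teacher adjusts both the difficulty and its own difficulty increment: the
move set is {decrement, stay, increment} x {shrink, keep, grow}, where
shrink/grow divide/multiply the increment by a growth factor within fixed
bounds.  An experimenter supplies only an initial rough guess for the
increment; a good teacher repairs a bad guess on the fly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .student import DEFAULT_REWARD, StudentParams, StudentState, run_interaction
from .teachers import CurriculumResult, Move
from .transcript import RateTracker, Transcript, TranscriptEntry

__all__ = [
    "evaluate_cont_policy",
    "evolve_cont_policy",
    "IncrementOp",
    "ContTeacherAction",
    "ContinuousSpec",
    "ContAdpPolicy",
    "micro_steps",
    "make_micro_params",
    "cont_run_interaction",
    "cont_adp_decide",
    "ContTeacher",
    "ContIncTeacher",
    "ContAdpTeacher",
    "run_continuous_curriculum",
]


class IncrementOp(IntEnum):
    SHRINK = -1
    KEEP = 0
    GROW = 1


@dataclass(frozen=True)
class ContTeacherAction:
    """One of the nine continuous-teacher actions."""

    move: Move
    increment_op: IncrementOp = IncrementOp.KEEP


@dataclass
class ContinuousSpec:
    """Continuous-task definition.

    ``grid`` is the micro-step size used to realise real-valued
    difficulties; ``initial_increment`` is the experimenter's rough guess
    delta_0 for the difficulty step; shrink/grow scale the running
    increment by ``1/growth`` and ``growth`` inside
    [increment_min, increment_max].
    """

    max_difficulty: float = 5.0
    grid: float = 0.25
    initial_increment: float = 1.0
    growth: float = 2.0
    increment_min: float = 0.25
    increment_max: float = 2.0
    tau: float = 0.85
    attempts_per_interaction: int = 10
    budget: int = 1500
    beta: float = 0.1
    n_step: int = 2                   # K of the student's K-step TD rule

    def __post_init__(self) -> None:
        if not (0.0 < self.grid <= self.increment_min <= self.initial_increment
                <= self.increment_max):
            raise ValueError(
                "need 0 < grid <= increment_min <= initial_increment <= increment_max")
        if self.max_difficulty <= 0:
            raise ValueError("max_difficulty must be > 0")
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must be in (0, 1)")
        if self.growth <= 1.0:
            raise ValueError("growth must be > 1")


@dataclass
class ContAdpPolicy:
    """Four-threshold decision tree returning one of the nine actions.

    * s_hat >= theta_hi: increment difficulty; grow the increment too when
      progress is fast (delta_s_hat >= mu_hi).
    * else if delta_s_hat >= mu_lo: stay (the student is still learning).
    * else: decrement; when competence has fallen low (s_hat < theta_lo)
      the increment is also shrunk — the overshoot was too large.
    """

    theta_hi: float = 0.85
    theta_lo: float = 0.5
    mu_lo: float = 0.005
    mu_hi: float = 0.15

    def to_dict(self) -> dict:
        return {"theta_hi": self.theta_hi, "theta_lo": self.theta_lo,
                "mu_lo": self.mu_lo, "mu_hi": self.mu_hi}

    @classmethod
    def from_dict(cls, d: dict) -> "ContAdpPolicy":
        return cls(**{k: float(d[k]) for k in
                      ("theta_hi", "theta_lo", "mu_lo", "mu_hi")})


def micro_steps(d: float, grid: float) -> int:
    """Number of micro-steps realising difficulty ``d`` (ceil with fp guard)."""
    return int(math.ceil(round(d / grid, 9)))


def make_micro_params(eps: float, alpha: float, spec: ContinuousSpec,
                      reward: float = DEFAULT_REWARD) -> StudentParams:
    """Micro-step chain parameters for the full task: bias eps*grid per step."""
    n = micro_steps(spec.max_difficulty, spec.grid)
    return StudentParams.constant_bias(n, eps * spec.grid, alpha, reward=reward)


def cont_run_interaction(
    state: StudentState,
    params: StudentParams,
    d: float,
    spec: ContinuousSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, StudentState]:
    """One interaction block at difficulty ``d``: T episodes on the
    ceil(d/grid)-step micro-chain with the K-step TD student."""
    if not (0.0 < d <= spec.max_difficulty + 1e-9):
        raise ValueError(f"difficulty {d} outside (0, {spec.max_difficulty}]")
    k = micro_steps(d, spec.grid)
    return run_interaction(state, params, k, spec.attempts_per_interaction,
                           rng, n_step=spec.n_step)


def cont_adp_decide(s_hat: float, delta_s_hat: float,
                    policy: ContAdpPolicy) -> ContTeacherAction:
    """Nine-action decision over the transcript features."""
    if s_hat >= policy.theta_hi:
        op = IncrementOp.GROW if delta_s_hat >= policy.mu_hi else IncrementOp.KEEP
        return ContTeacherAction(Move.INCREMENT, op)
    if delta_s_hat >= policy.mu_lo:
        return ContTeacherAction(Move.STAY, IncrementOp.KEEP)
    op = IncrementOp.SHRINK if s_hat < policy.theta_lo else IncrementOp.KEEP
    return ContTeacherAction(Move.DECREMENT, op)


class ContTeacher:
    """Interface for continuous teachers: track and adjust (d, increment)."""

    name = "cont-teacher"

    def reset(self, spec: ContinuousSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng
        self.increment = spec.initial_increment

    def initial_difficulty(self) -> float:
        return min(self.spec.initial_increment, self.spec.max_difficulty)

    def observe(self, d, outcomes, s_hat, delta_s_hat) -> None:
        pass

    def next_difficulty(self, d: float) -> float:
        raise NotImplementedError

    def _apply(self, d: float, action: ContTeacherAction) -> float:
        s = self.spec
        if action.increment_op == IncrementOp.SHRINK:
            self.increment = max(self.increment / s.growth, s.increment_min)
        elif action.increment_op == IncrementOp.GROW:
            self.increment = min(self.increment * s.growth, s.increment_max)
        d = d + int(action.move) * self.increment
        return float(min(max(d, s.grid), s.max_difficulty))


class ContIncTeacher(ContTeacher):
    """Fixed-increment incremental teacher: the rough guess is never revised."""

    name = "cont-inc"

    def observe(self, d, outcomes, s_hat, delta_s_hat):
        self._s = s_hat

    def next_difficulty(self, d: float) -> float:
        move = Move.INCREMENT if self._s >= self.spec.tau else Move.STAY
        return self._apply(d, ContTeacherAction(move, IncrementOp.KEEP))


class ContAdpTeacher(ContTeacher):
    name = "cont-adp"

    def __init__(self, policy: ContAdpPolicy | None = None):
        self.policy = policy or ContAdpPolicy()

    def observe(self, d, outcomes, s_hat, delta_s_hat):
        self._s, self._ds = s_hat, delta_s_hat

    def next_difficulty(self, d: float) -> float:
        return self._apply(d, cont_adp_decide(self._s, self._ds, self.policy))


def run_continuous_curriculum(
    teacher: ContTeacher,
    eps: float,
    alpha: float,
    spec: ContinuousSpec,
    rng: np.random.Generator,
    reward: float = DEFAULT_REWARD,
    record_q: bool = True,
    seed: int | None = None,
) -> CurriculumResult:
    """Teacher-student loop on the continuous task; terminates when the
    student's EMA success at the full difficulty D reaches tau."""
    params = make_micro_params(eps, alpha, spec, reward=reward)
    state = StudentState.naive(params.n_steps)
    tracker = RateTracker(beta=spec.beta)
    teacher.reset(spec, rng)
    d = teacher.initial_difficulty()
    transcript = Transcript()
    levels, s_hats, dss = [], [], []
    q_hist = [] if record_q else None
    completed = False
    t = 0
    for t in range(1, spec.budget + 1):
        outcomes, state = cont_run_interaction(state, params, d, spec, rng)
        s_hat, ds = tracker.observe(d, outcomes)
        teacher.observe(d, outcomes, s_hat, ds)
        levels.append(d)
        s_hats.append(s_hat)
        dss.append(ds)
        if q_hist is not None:
            q_hist.append(state.q.copy())
        transcript.append(TranscriptEntry(
            t=t, level=d, outcomes=list(map(int, outcomes)),
            s_hat=s_hat, delta_s_hat=ds,
        ))
        if abs(d - spec.max_difficulty) < 1e-9 and s_hat >= spec.tau:
            completed = True
            break
        d = teacher.next_difficulty(d)
    return CurriculumResult(
        completed=completed,
        interactions_used=t,
        levels=levels,
        s_hats=s_hats,
        delta_s_hats=dss,
        transcript=transcript,
        q_history=np.asarray(q_hist) if q_hist is not None else None,
        seed=seed,
    )


CONT_POLICY_BOUNDS = {
    "theta_hi": (0.5, 0.99),
    "theta_lo": (0.05, 0.8),
    "mu_lo": (-0.2, 0.2),
    "mu_hi": (0.0, 0.4),
}


def evaluate_cont_policy(
    policy: ContAdpPolicy,
    spec: ContinuousSpec,
    eps_grid=(-1.5, -2.0),
    n_seeds: int = 3,
    alpha: float = 0.1,
    dnf_penalty: float | None = None,
) -> float:
    """Mean completion time of a continuous ADP policy over an eps grid;
    deterministic in (policy, grid, seeds), DNF runs cost ``dnf_penalty``."""
    if dnf_penalty is None:
        dnf_penalty = 2.0 * spec.budget
    times = []
    for eps in eps_grid:
        for s in range(n_seeds):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(round((eps + 100.0) * 1000)), s, 1]))
            res = run_continuous_curriculum(ContAdpTeacher(policy), eps, alpha,
                                            spec, rng, record_q=False)
            times.append(res.interactions_used if res.completed else dnf_penalty)
    return float(np.mean(times))


def evolve_cont_policy(
    spec: ContinuousSpec,
    rng: np.random.Generator,
    population: int = 12,
    generations: int = 20,
    eps_grid=(-1.5, -2.0),
    n_seeds: int = 3,
) -> tuple[ContAdpPolicy, list]:
    """Fit the nine-action tree's four thresholds with the shared DE optimiser."""
    from .evolve import differential_evolution

    names = list(CONT_POLICY_BOUNDS)
    bounds = np.asarray([CONT_POLICY_BOUNDS[k] for k in names])

    def objective(x):
        pol = ContAdpPolicy(**dict(zip(names, map(float, x))))
        return evaluate_cont_policy(pol, spec, eps_grid, n_seeds)

    best_x, _, history = differential_evolution(
        objective, bounds, rng, population=population, generations=generations)
    return ContAdpPolicy(**dict(zip(names, map(float, best_x)))), history
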
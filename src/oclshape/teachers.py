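"""Discrete curriculum teachers and the teacher-student interaction loop.

A curriculum over difficulty levels 1..N is driven by a teacher that, after
every interaction (a block of T episodes at one level), chooses the next
level from the transcript alone.  Implemented teachers:

* ``IncTeacher`` — incremental: raise difficulty when the EMA success rate
  at the current level exceeds the target threshold tau; never lower it.
* ``RandTeacher`` — pick a level uniformly at random each interaction.
* ``AdpTeacher`` — adaptive heuristic on (s_hat, delta_s_hat): increment
  when estimated success is high, stay while the student is still learning,
  decrement on signs of significant extinction.
* ``LearningProgressTeacher`` — four task-selection baselines that chase
  the steepest success-rate slope (best-effort re-implementations).

The POMCP planner lives in :mod:`oclshape.pomcp` and plugs into the same
``Teacher`` interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .student import StudentParams, StudentState, episode_success_prob, run_interaction
from .transcript import RateTracker, Transcript, TranscriptEntry

__all__ = [
    "Move",
    "CurriculumSpec",
    "ADPPolicy",
    "CurriculumResult",
    "Teacher",
    "IncTeacher",
    "RandTeacher",
    "AdpTeacher",
    "LearningProgressTeacher",
    "inc_decide",
    "adp_decide",
    "rand_decide",
    "lp_baseline_decide",
    "run_curriculum",
]


class Move(IntEnum):
    """Discrete teacher actions; the resulting level is clamped to [1, N]."""

    DECREMENT = -1
    STAY = 0
    INCREMENT = 1


@dataclass
class CurriculumSpec:
    """Experiment definition the teacher is given up front.

    ``tau`` is the target success rate on the full task (level N); the
    curriculum terminates successfully once the EMA estimate at level N
    reaches it.  ``budget`` caps the number of teacher-student interactions.
    """

    n_levels: int = 10
    attempts_per_interaction: int = 10
    tau: float = 0.85
    budget: int = 1500
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.attempts_per_interaction < 1 or self.budget < 1:
            raise ValueError("n_levels, attempts_per_interaction and budget must be >= 1")
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "attempts_per_interaction": self.attempts_per_interaction,
            "tau": self.tau,
            "budget": self.budget,
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurriculumSpec":
        return cls(**{k: d[k] for k in
                      ("n_levels", "attempts_per_interaction", "tau", "budget", "beta")
                      if k in d})


@dataclass
class ADPPolicy:
    """Two-threshold decision tree over (s_hat, delta_s_hat).

    Rules, evaluated in order: increment if ``s_hat >= theta_inc``; else
    stay if ``delta_s_hat >= mu`` (the student is still making progress);
    else decrement (significant extinction).
    """

    theta_inc: float = 0.85
    mu: float = -0.01
    beta: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_inc < 1.0):
            raise ValueError("theta_inc must be in (0, 1)")

    def to_dict(self) -> dict:
        d = {"theta_inc": self.theta_inc, "mu": self.mu}
        if self.beta is not None:
            d["beta"] = self.beta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ADPPolicy":
        return cls(theta_inc=float(d["theta_inc"]), mu=float(d["mu"]),
                   beta=float(d["beta"]) if "beta" in d and d["beta"] is not None else None)


@dataclass
class CurriculumResult:
    """Full log of one curriculum run (diagnostics included)."""

    completed: bool
    interactions_used: int
    levels: list
    s_hats: list
    delta_s_hats: list
    transcript: Transcript
    q_history: np.ndarray | None = None
    true_success_prob_final: list = field(default_factory=list)
    seed: int | None = None


def inc_decide(s_hat: float, spec: CurriculumSpec) -> Move:
    """Incremental rule: INCREMENT iff s_hat >= tau, else STAY; never DECREMENT."""
    return Move.INCREMENT if s_hat >= spec.tau else Move.STAY


def adp_decide(s_hat: float, delta_s_hat: float, policy: ADPPolicy) -> Move:
    """Adaptive rule over the transcript features (s_hat, delta_s_hat)."""
    if s_hat >= policy.theta_inc:
        return Move.INCREMENT
    if delta_s_hat >= policy.mu:
        return Move.STAY
    return Move.DECREMENT


def rand_decide(spec: CurriculumSpec, rng: np.random.Generator) -> int:
    """Uniform random level in {1..N}."""
    return int(rng.integers(1, spec.n_levels + 1))


class Teacher:
    """Interface: observe each interaction, then propose the next level."""

    name = "teacher"

    def reset(self, spec: CurriculumSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng

    def initial_level(self) -> int:
        return 1  # curricula begin with the simplest version of the task

    def observe(self, level: int, outcomes: np.ndarray, s_hat: float,
                delta_s_hat: float) -> None:
        pass

    def next_level(self, level: int) -> int:
        raise NotImplementedError

    def _clamp(self, level: int) -> int:
        return int(min(max(level, 1), self.spec.n_levels))


class IncTeacher(Teacher):
    name = "inc"

    def observe(self, level, outcomes, s_hat, delta_s_hat):
        self._s = s_hat

    def next_level(self, level: int) -> int:
        return self._clamp(level + inc_decide(self._s, self.spec))


class RandTeacher(Teacher):
    name = "rand"

    def next_level(self, level: int) -> int:
        return rand_decide(self.spec, self.rng)


class AdpTeacher(Teacher):
    name = "adp"

    def __init__(self, policy: ADPPolicy | None = None):
        self.policy = policy or ADPPolicy()

    def observe(self, level, outcomes, s_hat, delta_s_hat):
        self._s, self._ds = s_hat, delta_s_hat

    def next_level(self, level: int) -> int:
        return self._clamp(level + adp_decide(self._s, self._ds, self.policy))


LP_VARIANTS = ("online", "naive", "window", "sampling")


def _argmax_random_ties(values: np.ndarray, rng: np.random.Generator) -> int:
    m = np.max(values)
    idx = np.flatnonzero(values >= m - 1e-12)
    return int(idx[rng.integers(len(idx))])


def lp_baseline_decide(
    score_histories: dict,
    n_levels: int,
    variant: str,
    rng: np.random.Generator,
    epsilon: float = 0.1,
    window: int = 5,
    online_weight: float = 0.3,
    buffer_size: int = 10,
) -> int:
    """Learning-progress task selection over per-level score histories.

    ``score_histories`` maps level -> list of observed block success rates
    (in visit order).  Each variant estimates per-level learning progress
    (slope of the score curve) and picks the level with the largest
    absolute progress; greedy variants explore with probability
    ``epsilon``.  Levels with too little history are prioritised so every
    level is sampled at least twice before slopes are compared.
    """
    if variant not in LP_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if n_levels == 1:
        return 1
    # force initial exploration: any level with < 2 observations
    short = [lv for lv in range(1, n_levels + 1)
             if len(score_histories.get(lv, [])) < 2]
    if short:
        return short[int(rng.integers(len(short)))]

    progress = np.zeros(n_levels)
    for lv in range(1, n_levels + 1):
        h = score_histories[lv]
        diffs = np.diff(h)
        if variant == "naive":
            progress[lv - 1] = diffs[-1]
        elif variant == "online":
            p = 0.0
            for d in diffs:
                p = (1.0 - online_weight) * p + online_weight * d
            progress[lv - 1] = p
        elif variant == "window":
            hw = np.asarray(h[-window:])
            x = np.arange(len(hw), dtype=float)
            progress[lv - 1] = np.polyfit(x, hw, 1)[0]
        else:  # sampling: draw one recent slope at random per level
            buf = diffs[-buffer_size:]
            progress[lv - 1] = buf[int(rng.integers(len(buf)))]

    if variant != "sampling" and rng.random() < epsilon:
        return int(rng.integers(1, n_levels + 1))
    return 1 + _argmax_random_ties(np.abs(progress), rng)


class LearningProgressTeacher(Teacher):
    """Experimental: greedy/sampling learning-progress baselines."""

    def __init__(self, variant: str = "online", epsilon: float = 0.1):
        if variant not in LP_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.epsilon = epsilon
        self.name = f"lp-{variant}"

    def reset(self, spec, rng):
        super().reset(spec, rng)
        self.histories: dict = {}

    def observe(self, level, outcomes, s_hat, delta_s_hat):
        self.histories.setdefault(int(level), []).append(float(np.mean(outcomes)))

    def next_level(self, level: int) -> int:
        return lp_baseline_decide(
            self.histories, self.spec.n_levels, self.variant, self.rng,
            epsilon=self.epsilon,
        )


def run_curriculum(
    teacher: Teacher,
    params: StudentParams,
    spec: CurriculumSpec,
    rng: np.random.Generator,
    record_q: bool = True,
    seed: int | None = None,
) -> CurriculumResult:
    """Run the teacher-student loop until the student passes the full task
    or the interaction budget is exhausted.

    Termination is evaluated on the observable estimate ``s_hat`` at level
    N (not the hidden true success probability); the true probability on
    the full task is logged alongside for honest evaluation.
    """
    beta = spec.beta
    if isinstance(teacher, AdpTeacher) and teacher.policy.beta is not None:
        beta = teacher.policy.beta
    tracker = RateTracker(beta=beta)
    state = StudentState.naive(params.n_steps)
    teacher.reset(spec, rng)
    level = teacher.initial_level()
    transcript = Transcript()
    levels, s_hats, dss, true_probs = [], [], [], []
    q_hist = [] if record_q else None
    completed = False
    t = 0
    for t in range(1, spec.budget + 1):
        level = int(min(max(level, 1), spec.n_levels))
        outcomes, state = run_interaction(
            state, params, level, spec.attempts_per_interaction, rng
        )
        s_hat, ds = tracker.observe(level, outcomes)
        teacher.observe(level, outcomes, s_hat, ds)
        levels.append(level)
        s_hats.append(s_hat)
        dss.append(ds)
        true_probs.append(episode_success_prob(state, params, params.n_steps))
        if q_hist is not None:
            q_hist.append(state.q.copy())
        transcript.append(TranscriptEntry(
            t=t, level=level, outcomes=list(map(int, outcomes)),
            s_hat=s_hat, delta_s_hat=ds,
        ))
        if level == spec.n_levels and s_hat >= spec.tau:
            completed = True
            break
        level = teacher.next_level(level)
    return CurriculumResult(
        completed=completed,
        interactions_used=t,
        levels=levels,
        s_hats=s_hats,
        delta_s_hats=dss,
        transcript=transcript,
        q_history=np.asarray(q_hist) if q_hist is not None else None,
        true_success_prob_final=true_probs,
        seed=seed,
    )
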
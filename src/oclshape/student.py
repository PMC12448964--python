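"""Sequence-learning student: logistic action selection + temporal-difference updates.

The student must execute a chain of correct actions to obtain a single
terminal reward.  At step ``i`` the correct action is taken with probability
``sigma(q_i + eps_i)`` where ``eps_i`` is a fixed innate bias (log-odds of
the correct action before any learning) and ``q_i`` is a learned action
value, initialised to zero.  Values are updated with an online n-step
TD rule (n=1, i.e. TD(0), by default); only the correct action's value is
stored — all incorrect actions share an implicit value of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StudentParams",
    "StudentState",
    "EpisodeResult",
    "logistic_success_prob",
    "bias_from_action_count",
    "episode_success_prob",
    "run_episode",
    "run_interaction",
    "DEFAULT_REWARD",
]

#: Default terminal reward magnitude.  Sets the asymptotic action value a
#: step converges to under repeated reinforcement: the per-step success
#: ceiling is sigma(R + eps), so R must comfortably exceed the log-odds
#: needed to pass the full task at threshold (about 4.1 + |eps| for
#: tau = 0.85, N = 10).  See docs/methods.md for how the default was fixed.
DEFAULT_REWARD = 6.0


def logistic_success_prob(q_i: float, eps_i: float) -> float:
    """Probability of the correct action at one step: ``sigma(q_i + eps_i)``.

    Strictly inside (0, 1) and monotone increasing in both arguments.
    """
    if not (math.isfinite(q_i) and math.isfinite(eps_i)):
        raise ValueError("q_i and eps_i must be finite")
    z = q_i + eps_i
    # numerically stable logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def bias_from_action_count(n_actions: int) -> float:
    """Innate bias for a uniform naive policy over ``n_actions`` choices.

    With K equiprobable actions of which one is correct, the log-odds of
    the correct action is ``-log(K - 1)``.
    """
    if n_actions < 2:
        raise ValueError("need at least 2 actions (one correct, one incorrect)")
    return -math.log(n_actions - 1)


@dataclass
class StudentParams:
    """Hidden ground-truth parameters of the simulated learner.

    Parameters
    ----------
    n_steps
        N, the length of the full action sequence.
    eps
        Innate biases, one per step (log-odds units).  A scalar is
        broadcast to all steps.
    alpha
        TD learning rate, in (0, 1].  ``alpha = 0`` is accepted and turns
        learning off (useful for analytic checks).
    reward
        Terminal reward magnitude R delivered on completing the assigned
        sub-task.
    """

    n_steps: int
    eps: np.ndarray
    alpha: float
    reward: float = DEFAULT_REWARD

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self.eps = np.broadcast_to(
            np.asarray(self.eps, dtype=float), (self.n_steps,)
        ).copy()
        if not np.all(np.isfinite(self.eps)):
            raise ValueError("eps must be finite")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")

    @classmethod
    def constant_bias(
        cls,
        n_steps: int,
        eps: float,
        alpha: float,
        reward: float = DEFAULT_REWARD,
    ) -> "StudentParams":
        """Convenience constructor for the homogeneous-bias student."""
        return cls(n_steps=n_steps, eps=np.full(n_steps, float(eps)), alpha=alpha, reward=reward)

    def to_dict(self) -> dict:
        eps = self.eps
        eps_out = float(eps[0]) if np.all(eps == eps[0]) else [float(e) for e in eps]
        return {
            "n_steps": int(self.n_steps),
            "eps": eps_out,
            "alpha": float(self.alpha),
            "reward": float(self.reward),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudentParams":
        return cls(
            n_steps=int(d["n_steps"]),
            eps=np.asarray(d["eps"], dtype=float),
            alpha=float(d["alpha"]),
            reward=float(d.get("reward", DEFAULT_REWARD)),
        )


@dataclass
class StudentState:
    """Learned action values ``q_1..q_N`` (log-odds units), zero at birth."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).copy()
        if self.q.ndim != 1:
            raise ValueError("q must be a vector")

    @classmethod
    def naive(cls, n_steps: int) -> "StudentState":
        return cls(q=np.zeros(n_steps))

    def copy(self) -> "StudentState":
        return StudentState(q=self.q)


@dataclass
class EpisodeResult:
    """One episode: did the student reach the reward, and how far did it get.

    ``trace[i]`` is True where step ``i+1`` was executed correctly; only the
    final entry may be False (an incorrect action ends the episode).
    """

    outcome: int
    steps_taken: int
    trace: list = field(default_factory=list)


def episode_success_prob(state: StudentState, params: StudentParams, k: int) -> float:
    """Analytic probability of completing a level-``k`` episode: prod sigma(q_i+eps_i)."""
    _check_level(k, params.n_steps)
    z = state.q[:k] + params.eps[:k]
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z))
    return float(np.prod(p))


def _check_level(k: int, n_steps: int) -> None:
    if not (1 <= k <= n_steps):
        raise ValueError(f"level k={k} out of range [1, {n_steps}]")


def run_episode(
    state: StudentState,
    params: StudentParams,
    k: int,
    rng: np.random.Generator,
    n_step: int = 1,
) -> tuple[EpisodeResult, StudentState]:
    """Simulate one episode at level ``k`` and apply TD updates in place.

    The student attempts steps 1..k in order; an incorrect action terminates
    the episode without reward; completing all ``k`` steps delivers reward R
    at the final step.  Updates follow an online n-step TD rule with student
    discount 1: for each correctly executed step ``i`` (1-indexed),

        G_i = R*[success and k - i < n_step] + V_{i+n_step}
        q_i <- q_i + alpha * (G_i - q_i)

    where ``V_j = q_j`` if step ``j`` was still attempted in this episode
    and 0 past termination.  Incorrectly executed steps update nothing
    (incorrect-action values are fixed at zero).  Because each attempted
    step is visited once and bootstrap targets lie strictly ahead, the
    online rule is applied equivalently as a single post-episode pass over
    the realised trace using pre-episode values.
    """
    _check_level(k, params.n_steps)
    if n_step < 1:
        raise ValueError("n_step must be >= 1")
    q = state.q
    eps = params.eps
    trace: list[bool] = []
    for i in range(k):
        p = logistic_success_prob(q[i], eps[i])
        correct = rng.random() < p
        trace.append(correct)
        if not correct:
            break
    n_attempted = len(trace)
    success = n_attempted == k and trace[-1]
    if params.alpha > 0.0:
        qpre = q[:n_attempted].copy()
        alpha = params.alpha
        for i in range(n_attempted):
            if not trace[i]:
                continue
            boot_idx = i + n_step
            boot = qpre[boot_idx] if boot_idx < n_attempted else 0.0
            g = boot
            if success and (k - 1) - i < n_step:
                g += params.reward
            q[i] += alpha * (g - q[i])
    return EpisodeResult(outcome=int(success), steps_taken=n_attempted, trace=trace), state


def run_interaction(
    state: StudentState,
    params: StudentParams,
    k: int,
    n_attempts: int,
    rng: np.random.Generator,
    n_step: int = 1,
) -> tuple[np.ndarray, StudentState]:
    """Run ``n_attempts`` consecutive episodes at level ``k`` (learning between
    episodes); returns the ordered binary outcome block and the updated state."""
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    outcomes = np.empty(n_attempts, dtype=np.int64)
    for t in range(n_attempts):
        res, state = run_episode(state, params, k, rng, n_step=n_step)
        outcomes[t] = res.outcome
    return outcomes, state
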
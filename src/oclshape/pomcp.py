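"""Near-optimal teacher: particle-filter inference + Monte Carlo tree search.

The teacher's decision problem is a POMDP: the student's action values,
innate bias and learning rate are hidden; the observation after assigning a
level is the block of binary outcomes.  The belief over (q, eps, alpha) is
a weighted particle set updated by Bayes' rule; planning is POMCP — UCB1
tree search over {decrement, stay, increment} with observation nodes
branching on the block's success count, Monte Carlo rollouts, and a unit
reward (discounted) when the student's estimated success rate on the full
task crosses the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log, sqrt

import numpy as np

from .student import StudentParams, StudentState, run_interaction
from .teachers import CurriculumSpec, Move, Teacher, inc_decide
from .transcript import RateTracker

__all__ = [
    "PriorSpec",
    "POMCPConfig",
    "ParticleBelief",
    "sample_prior",
    "belief_update",
    "pomcp_search",
    "teacher_reward",
    "PomcpTeacher",
]


@dataclass
class PriorSpec:
    """Uniform priors over the student's hidden bias and learning rate."""

    eps_low: float = -3.0
    eps_high: float = 0.0
    alpha_low: float = 0.01
    alpha_high: float = 0.5

    def __post_init__(self) -> None:
        if self.eps_low > self.eps_high:
            raise ValueError("eps prior bounds must satisfy low <= high")
        if not (0.0 < self.alpha_low <= self.alpha_high <= 1.0):
            raise ValueError("alpha prior support must lie in (0, 1]")


@dataclass
class POMCPConfig:
    n_particles: int = 1000
    n_simulations: int = 500
    ucb_c: float = sqrt(2.0)
    gamma_teacher: float = 0.98
    max_depth: int = 30
    rollout_policy: str = "inc"
    ess_fraction: float = 0.5  # resample when ESS falls below this fraction
    jitter_eps: float = 0.05
    jitter_alpha: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_particles, self.n_simulations, self.max_depth) < 1:
            raise ValueError("n_particles, n_simulations, max_depth must be >= 1")
        if not (0.0 < self.gamma_teacher < 1.0):
            raise ValueError("gamma_teacher must be in (0, 1)")
        if self.ucb_c < 0:
            raise ValueError("ucb_c must be >= 0")


class ParticleBelief:
    """Weighted particles over (q vector, eps, alpha); vectorised internally.

    The bias is assumed homogeneous across steps within each particle
    (constant-eps hypothesis); ``q`` starts at zero, which is known at the
    start of training.
    """

    def __init__(self, q: np.ndarray, eps: np.ndarray, alpha: np.ndarray,
                 weights: np.ndarray, prior: PriorSpec, reward: float,
                 jitter_eps: float = 0.05, jitter_alpha: float = 0.01):
        self.jitter_eps = jitter_eps
        self.jitter_alpha = jitter_alpha
        self.q = np.asarray(q, dtype=float)
        self.eps = np.asarray(eps, dtype=float)
        self.alpha = np.asarray(alpha, dtype=float)
        w = np.asarray(weights, dtype=float)
        self.weights = w / w.sum()
        self.prior = prior
        self.reward = reward

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def n_steps(self) -> int:
        return self.q.shape[1]

    def ess(self) -> float:
        """Effective sample size 1 / sum(w^2)."""
        return float(1.0 / np.sum(self.weights**2))

    def mean_eps(self) -> float:
        return float(np.dot(self.weights, self.eps))

    def mean_alpha(self) -> float:
        return float(np.dot(self.weights, self.alpha))

    def mean_q(self) -> np.ndarray:
        return self.weights @ self.q

    def sample_index(self, rng: np.random.Generator) -> int:
        return int(rng.choice(len(self), p=self.weights))

    def particle_params(self, i: int, n_steps: int | None = None) -> StudentParams:
        n = n_steps or self.n_steps
        return StudentParams.constant_bias(n, self.eps[i], self.alpha[i],
                                           reward=self.reward)

    # -- Bayes update -----------------------------------------------------

    def update(self, level: int, outcomes, rng: np.random.Generator) -> None:
        """Condition on one interaction block, outcome by outcome, in order.

        For each outcome the particle weight is multiplied by the particle's
        predicted probability of that outcome, then the particle's q is
        advanced by simulating the student's TD update given the outcome
        (one sampled step-trace consistent with it — unbiased in the
        particle limit rather than an exact trace marginalisation).
        Systematic resampling with Gaussian reinvigoration on (eps, alpha)
        restores particle diversity when the ESS drops below half the set.
        """
        k = int(level)
        n, _ = self.q.shape
        logw = np.log(self.weights)
        for x in np.asarray(outcomes, dtype=int):
            z = self.q[:, :k] + self.eps[:, None]
            sig = 1.0 / (1.0 + np.exp(-z))          # (n, k) per-step success
            p_succ = np.prod(sig, axis=1)
            p_obs = p_succ if x == 1 else 1.0 - p_succ
            if np.max(p_obs) <= 0.0:
                # every particle assigns probability zero to the observation
                warnings.warn("belief collapse: resampling hidden parameters from prior")
                self.eps = rng.uniform(self.prior.eps_low, self.prior.eps_high, n)
                self.alpha = rng.uniform(self.prior.alpha_low, self.prior.alpha_high, n)
                logw = np.full(n, -np.log(n))
            else:
                logw += np.log(np.maximum(p_obs, 1e-300))
            self._advance(sig, k, x, rng)
        w = np.exp(logw - logw.max())
        self.weights = w / w.sum()
        if self.ess() < 0.5 * n:
            self._resample(rng)

    def _advance(self, sig: np.ndarray, k: int, x: int, rng: np.random.Generator) -> None:
        """Advance every particle's q through one episode with outcome ``x``."""
        n = sig.shape[0]
        qpre = self.q[:, :k].copy()
        alpha = self.alpha
        if x == 1:
            # all k steps correct: TD(0) pass with pre-episode targets
            for i in range(k):
                boot = qpre[:, i + 1] if i + 1 < k else 0.0
                g = boot + (self.reward if i == k - 1 else 0.0)
                self.q[:, i] += alpha * (g - qpre[:, i])
        else:
            # sample the failure step f | failure, per particle
            prefix = np.cumprod(np.hstack([np.ones((n, 1)), sig[:, :-1]]), axis=1)
            pfail = prefix * (1.0 - sig)            # (n, k), sums to 1 - p_succ
            tot = pfail.sum(axis=1, keepdims=True)
            cdf = np.cumsum(pfail / np.maximum(tot, 1e-300), axis=1)
            u = rng.random((n, 1))
            f = (u > cdf).sum(axis=1)               # failure step index, 0-based
            # steps i < f were correct: q_i tracks q_{i+1} (no reward)
            for i in range(k - 1):
                mask = i < f
                self.q[mask, i] += alpha[mask] * (qpre[mask, i + 1] - qpre[mask, i])

    def _resample(self, rng: np.random.Generator) -> None:
        n = len(self)
        u = (rng.random() + np.arange(n)) / n       # systematic resampling
        idx = np.searchsorted(np.cumsum(self.weights), u)
        idx = np.clip(idx, 0, n - 1)
        self.q = self.q[idx]
        self.eps = np.clip(
            self.eps[idx] + rng.normal(0.0, self.jitter_eps, n),
            self.prior.eps_low, self.prior.eps_high,
        )
        self.alpha = np.clip(
            self.alpha[idx] + rng.normal(0.0, self.jitter_alpha, n),
            self.prior.alpha_low, self.prior.alpha_high,
        )
        self.weights = np.full(n, 1.0 / n)


def sample_prior(prior: PriorSpec, n: int, n_steps: int,
                 rng: np.random.Generator, reward: float | None = None) -> ParticleBelief:
    """Draw ``n`` particles: q = 0 (known at training start), (eps, alpha) ~ prior."""
    if n < 1:
        raise ValueError("need at least one particle")
    from .student import DEFAULT_REWARD

    return ParticleBelief(
        q=np.zeros((n, n_steps)),
        eps=rng.uniform(prior.eps_low, prior.eps_high, n),
        alpha=rng.uniform(prior.alpha_low, prior.alpha_high, n),
        weights=np.full(n, 1.0 / n),
        prior=prior,
        reward=DEFAULT_REWARD if reward is None else reward,
    )


def belief_update(belief: ParticleBelief, level: int, outcomes,
                  rng: np.random.Generator) -> ParticleBelief:
    """Functional wrapper around :meth:`ParticleBelief.update`."""
    belief.update(level, outcomes, rng)
    return belief


def teacher_reward(level: int, s_hat_final: float, spec: CurriculumSpec) -> int:
    """Unit reward iff the curriculum's termination condition is met."""
    return int(level == spec.n_levels and s_hat_final >= spec.tau)


# -- POMCP tree search ----------------------------------------------------

_MOVES = (Move.DECREMENT, Move.STAY, Move.INCREMENT)


class _Node:
    __slots__ = ("visits", "value", "children")

    def __init__(self):
        self.visits = 0
        self.value = 0.0
        self.children = {}


def _step_world(q, params, level, move, tracker, spec, rng):
    """Apply a teacher move in a simulated world; returns (level, obs, reward, done)."""
    level = int(min(max(level + int(move), 1), spec.n_levels))
    state = StudentState.__new__(StudentState)
    state.q = q  # in-place view: episodes mutate the simulated student
    outcomes, _ = run_interaction(state, params, level,
                                  spec.attempts_per_interaction, rng)
    s_hat, _ = tracker.observe(level, outcomes)
    r = teacher_reward(level, s_hat, spec)
    return level, int(outcomes.sum()), r, bool(r)


def _rollout(q, params, level, tracker, spec, cfg, rng, depth):
    """INC-rule rollout on the simulated tracker, discounted."""
    total, disc = 0.0, 1.0
    while depth < cfg.max_depth:
        move = inc_decide(tracker.value(level), spec)
        level, _, r, done = _step_world(q, params, level, move, tracker, spec, rng)
        total += disc * r
        if done:
            break
        disc *= cfg.gamma_teacher
        depth += 1
    return total


def pomcp_search(
    belief: ParticleBelief,
    level: int,
    spec: CurriculumSpec,
    config: POMCPConfig,
    rng: np.random.Generator,
    tracker: RateTracker | None = None,
) -> Move:
    """Choose the next move by POMCP.

    Each simulation draws a particle as the root world state, descends the
    tree picking moves by UCB1, branches observation nodes on the block's
    success count, expands one node per simulation with a rollout, and
    backs up discounted returns.  The returned move is the root action with
    the most visits.  ``tracker`` seeds the simulated success-rate
    estimates so that termination inside the search mirrors the real loop.
    """
    if config.n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    base_tracker = tracker.copy() if tracker is not None else RateTracker(spec.beta)
    root = _Node()
    for a in _MOVES:
        root.children[a] = _Node()

    for _ in range(config.n_simulations):
        i = belief.sample_index(rng)
        q = belief.q[i].copy()
        params = belief.particle_params(i)
        trk = base_tracker.copy()
        _simulate(root, q, params, int(level), trk, spec, config, rng, 0)

    visits = {a: root.children[a].visits for a in _MOVES}
    best = max(_MOVES, key=lambda a: (visits[a], -abs(int(a))))
    return best


def _simulate(node, q, params, level, tracker, spec, cfg, rng, depth):
    if depth >= cfg.max_depth:
        return 0.0
    # UCB1 action choice
    if node.visits == 0:
        a = _MOVES[rng.integers(3)]
    else:
        best_a, best_u = None, -np.inf
        for a in _MOVES:
            ch = node.children.setdefault(a, _Node())
            if ch.visits == 0:
                u = np.inf if cfg.ucb_c > 0 else ch.value
            else:
                u = ch.value + cfg.ucb_c * sqrt(log(node.visits + 1) / ch.visits)
            u += 1e-9 * rng.random()  # random tie-break
            if u > best_u:
                best_a, best_u = a, u
        a = best_a
    child = node.children.setdefault(a, _Node())
    new_level, obs, r, done = _step_world(q, params, level, a, tracker, spec, rng)
    if done:
        ret = float(r)
    else:
        onode = child.children.get(obs)
        if onode is None:
            child.children[obs] = onode = _Node()
            tail = _rollout(q, params, new_level, tracker, spec, cfg, rng, depth + 1)
            ret = r + cfg.gamma_teacher * tail
        else:
            ret = r + cfg.gamma_teacher * _simulate(
                onode, q, params, new_level, tracker, spec, cfg, rng, depth + 1
            )
    node.visits += 1
    child.visits += 1
    child.value += (ret - child.value) / child.visits
    return ret


class PomcpTeacher(Teacher):
    """Teacher that maintains a particle belief and plans with POMCP."""

    name = "pomcp"

    def __init__(self, config: POMCPConfig | None = None,
                 prior: PriorSpec | None = None, reward: float | None = None):
        self.config = config or POMCPConfig()
        self.prior = prior or PriorSpec()
        self._reward = reward
        self.diagnostics: list = []

    def reset(self, spec, rng):
        super().reset(spec, rng)
        self.tracker = RateTracker(spec.beta)
        self.belief = sample_prior(self.prior, self.config.n_particles,
                                   spec.n_levels, rng, reward=self._reward)
        self.diagnostics = []

    def observe(self, level, outcomes, s_hat, delta_s_hat):
        self.tracker.observe(level, outcomes)
        self.belief.update(level, outcomes, self.rng)
        self.diagnostics.append({
            "level": int(level),
            "ess": self.belief.ess(),
            "mean_eps": self.belief.mean_eps(),
            "mean_alpha": self.belief.mean_alpha(),
        })

    def next_level(self, level: int) -> int:
        move = pomcp_search(self.belief, level, self.spec, self.config,
                            self.rng, tracker=self.tracker)
        return self._clamp(level + int(move))
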
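"""Differential evolution of the adaptive teacher's decision thresholds.

The ADP heuristic has a handful of scalar parameters (the increment
threshold on s_hat, the extinction threshold on delta_s_hat, optionally the
EMA decay).  They are fit once by DE/rand/1/bin against simulated curricula
spanning a grid of innate biases, minimising the mean number of
teacher-student interactions to completion (with a did-not-finish penalty),
and then frozen for all benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .student import StudentParams
from .teachers import ADPPolicy, AdpTeacher, CurriculumSpec, run_curriculum

__all__ = ["EvolveConfig", "evaluate_policy", "de_optimize", "differential_evolution"]


@dataclass
class EvolveConfig:
    """DE hyperparameters plus the simulated training conditions."""

    population: int = 16
    generations: int = 40
    diff_weight: float = 0.7          # F
    crossover: float = 0.9            # CR
    bounds: dict = field(default_factory=lambda: {
        "theta_inc": (0.5, 0.99),
        "mu": (-0.2, 0.2),
    })
    eval_eps_grid: tuple = (-1.0, -1.5, -2.0)
    eval_seeds: int = 5
    budget: int = 800
    dnf_penalty: float | None = None  # default 2 * budget
    spec: CurriculumSpec | None = None
    alpha: float = 0.1
    aggregate: str = "mean"           # or "median"

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("DE needs a population of at least 4")
        if not (0.0 < self.crossover <= 1.0):
            raise ValueError("crossover rate CR must be in (0, 1]")
        if self.diff_weight <= 0:
            raise ValueError("differential weight F must be > 0")
        if self.dnf_penalty is None:
            self.dnf_penalty = 2.0 * self.budget

    def param_names(self) -> list:
        return list(self.bounds)

    def make_policy(self, x: np.ndarray) -> ADPPolicy:
        d = dict(zip(self.param_names(), map(float, x)))
        return ADPPolicy(theta_inc=d["theta_inc"], mu=d["mu"],
                         beta=d.get("beta"))


def evaluate_policy(policy: ADPPolicy, cfg: EvolveConfig,
                    rng: np.random.Generator | None = None) -> float:
    """Cost of a policy: aggregate completion time over the eps grid x seeds.

    Runs are seeded deterministically from (eps, seed index) only, so the
    cost is a pure function of the policy and config — duplicated seeds or
    re-evaluations give identical numbers.  Incomplete runs contribute
    ``dnf_penalty`` interactions.
    """
    spec = cfg.spec or CurriculumSpec(budget=cfg.budget)
    times = []
    for eps in cfg.eval_eps_grid:
        for s in range(cfg.eval_seeds):
            run_rng = np.random.default_rng(
                np.random.SeedSequence([int(round((eps + 100.0) * 1000)), s])
            )
            params = StudentParams.constant_bias(spec.n_levels, eps, cfg.alpha)
            res = run_curriculum(AdpTeacher(policy), params, spec, run_rng,
                                 record_q=False)
            times.append(res.interactions_used if res.completed
                         else float(cfg.dnf_penalty))
    agg = np.median if cfg.aggregate == "median" else np.mean
    return float(agg(times))


def differential_evolution(
    objective,
    bounds: np.ndarray,
    rng: np.random.Generator,
    population: int = 16,
    generations: int = 40,
    diff_weight: float = 0.7,
    crossover: float = 0.9,
) -> tuple[np.ndarray, float, list]:
    """Minimise ``objective`` over a box with DE/rand/1/bin.

    Returns (best vector, best cost, per-generation best-cost history).
    The history includes the initial population's best and is
    non-increasing by elitist selection.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be (n_params, 2) with low < high")
    d = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    pop = lo + rng.random((population, d)) * (hi - lo)
    cost = np.array([objective(x) for x in pop])
    history = [float(cost.min())]
    for _ in range(generations):
        for i in range(population):
            idx = [j for j in range(population) if j != i]
            a, b, c = pop[[idx[j] for j in rng.choice(len(idx), 3, replace=False)]]
            mutant = np.clip(a + diff_weight * (b - c), lo, hi)
            cross = rng.random(d) < crossover
            cross[rng.integers(d)] = True
            trial = np.where(cross, mutant, pop[i])
            tc = objective(trial)
            if tc <= cost[i]:
                pop[i], cost[i] = trial, tc
        history.append(float(cost.min()))
    best = int(np.argmin(cost))
    return pop[best].copy(), float(cost[best]), history


def de_optimize(cfg: EvolveConfig,
                rng: np.random.Generator) -> tuple[ADPPolicy, list]:
    """Evolve an ADPPolicy; returns the best policy and the cost history."""
    bounds = np.asarray([cfg.bounds[k] for k in cfg.param_names()])
    best_x, _, history = differential_evolution(
        lambda x: evaluate_policy(cfg.make_policy(x), cfg),
        bounds, rng,
        population=cfg.population, generations=cfg.generations,
        diff_weight=cfg.diff_weight, crossover=cfg.crossover,
    )
    return cfg.make_policy(best_x), history
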
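"""Reproducible experiment runner: benchmark sweeps and diagnostic exports.

Every run is seeded from a master seed plus its (teacher, eps, repeat)
coordinates, so results are independent of execution order and bit-identical
across re-runs of the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .continuous import ContAdpPolicy
from .student import StudentParams
from .teachers import (
    ADPPolicy,
    AdpTeacher,
    CurriculumResult,
    CurriculumSpec,
    IncTeacher,
    LearningProgressTeacher,
    RandTeacher,
    Teacher,
    run_curriculum,
)

__all__ = [
    "BenchmarkConfig",
    "make_teacher",
    "run_benchmark",
    "export_q_history",
    "detect_stripes",
    "default_adp_policy",
    "default_cont_adp_policy",
]

_POLICY_DIR = Path(__file__).parent / "policies"

TEACHER_NAMES = ("inc", "rand", "adp", "pomcp",
                 "lp-online", "lp-naive", "lp-window", "lp-sampling")


def default_adp_policy() -> ADPPolicy:
    """The frozen evolved ADP policy shipped with the package."""
    with open(_POLICY_DIR / "adp_default.json") as fh:
        return ADPPolicy.from_dict(json.load(fh))


def default_cont_adp_policy() -> ContAdpPolicy:
    """The frozen evolved continuous ADP policy shipped with the package."""
    with open(_POLICY_DIR / "cont_adp_default.json") as fh:
        return ContAdpPolicy.from_dict(json.load(fh))


def make_teacher(name: str, adp_policy: ADPPolicy | None = None,
                 pomcp_config=None) -> Teacher:
    """Teacher factory by benchmark id."""
    if name == "inc":
        return IncTeacher()
    if name == "rand":
        return RandTeacher()
    if name == "adp":
        return AdpTeacher(adp_policy or default_adp_policy())
    if name == "pomcp":
        from .pomcp import PomcpTeacher

        return PomcpTeacher(config=pomcp_config)
    if name.startswith("lp-"):
        return LearningProgressTeacher(variant=name[3:])
    raise ValueError(f"unknown teacher {name!r}; expected one of {TEACHER_NAMES}")


@dataclass
class BenchmarkConfig:
    teachers: list
    eps_grid: list
    repeats: int = 10
    spec: CurriculumSpec = field(default_factory=CurriculumSpec)
    alpha: float = 0.1
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.eps_grid:
            raise ValueError("eps grid must be nonempty")
        for t in self.teachers:
            if t not in TEACHER_NAMES:
                raise ValueError(f"unknown teacher {t!r}")


def _run_seed(cfg: BenchmarkConfig, ti: int, ei: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.master_seed), ti, ei, rep])
    )


def run_benchmark(cfg: BenchmarkConfig, record_q: bool = False) -> pd.DataFrame:
    """Run every (teacher, eps, repeat) cell; returns a tidy results table
    and, if ``cfg.out_dir`` is set, writes summary.csv plus per-run JSONL logs."""
    rows = []
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for ti, tname in enumerate(cfg.teachers):
        for ei, eps in enumerate(cfg.eps_grid):
            for rep in range(cfg.repeats):
                rng = _run_seed(cfg, ti, ei, rep)
                teacher = make_teacher(tname)
                params = StudentParams.constant_bias(
                    cfg.spec.n_levels, eps, cfg.alpha)
                res = run_curriculum(teacher, params, cfg.spec, rng,
                                     record_q=record_q)
                rows.append({
                    "teacher": tname, "eps": float(eps), "repeat": rep,
                    "completed": bool(res.completed),
                    "interactions_used": res.interactions_used,
                })
                if out:
                    log = out / f"{tname}_eps{eps:+.2f}_rep{rep}.jsonl"
                    log.write_text(res.transcript.to_jsonl())
    df = pd.DataFrame(rows)
    if out:
        df.to_csv(out / "summary.csv", index=False)
    return df


def export_q_history(result: CurriculumResult, path: str | Path) -> pd.DataFrame:
    """Write the interactions x N action-value matrix plus the level
    trajectory — the data behind the striped reinforcement/extinction plots."""
    if result.q_history is None:
        raise ValueError("run was executed with record_q=False; no q history")
    qh = np.asarray(result.q_history)
    df = pd.DataFrame(qh, columns=[f"q{i+1}" for i in range(qh.shape[1])])
    df.insert(0, "t", np.arange(1, len(df) + 1))
    df["level"] = result.levels
    df.to_csv(path, index=False)
    return df


def detect_stripes(result: CurriculumResult, tau: float,
                   drop: float = -0.1, horizon: int = 3,
                   beta: float = 0.1) -> list:
    """Find (increment, transient drop, recovery) triples in a run log.

    A stripe is a level increment followed within ``horizon`` interactions
    by a drop of at least ``|drop|`` in a level-agnostic EMA of episode
    outcomes, with that EMA later recovering to >= tau.  The level-agnostic
    stream is used because per-level estimates start fresh on first visit
    and so cannot exhibit the transient dip.  A qualitative signature of
    alternating reinforcement and extinction; test-only diagnostics.
    """
    levels = list(result.levels)
    g = 0.0
    global_ema = []
    for e in result.transcript.entries:
        for x in e.outcomes:
            g = (1.0 - beta) * g + beta * x
        global_ema.append(g)
    stripes = []
    for t in range(1, len(levels)):
        if levels[t] <= levels[t - 1]:
            continue
        base = global_ema[t - 1]
        t_drop = next((u for u in range(t, min(t + horizon, len(levels)))
                       if global_ema[u] - base <= drop), None)
        if t_drop is None:
            continue
        t_rec = next((u for u in range(t_drop + 1, len(levels))
                      if global_ema[u] >= tau), None)
        if t_rec is not None:
            stripes.append((t, t_drop, t_rec))
    return stripes
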
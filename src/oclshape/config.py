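"""YAML/JSON configuration loading and saving.

A config file describes a student, a curriculum and optionally a teacher
policy, e.g.::

    student:
      n_steps: 10
      eps: -1.5        # scalar or per-step list
      alpha: 0.1
    curriculum:
      n_levels: 10
      attempts_per_interaction: 10
      tau: 0.85
      budget: 1500
    adp_policy:        # optional; defaults to the shipped evolved policy
      theta_inc: 0.9
      mu: 0.01
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .continuous import ContAdpPolicy, ContinuousSpec
from .student import StudentParams
from .teachers import ADPPolicy, CurriculumSpec

__all__ = [
    "load_config",
    "save_config",
    "load_policy",
    "save_policy",
    "parse_student",
    "parse_curriculum",
    "parse_continuous",
]


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def parse_student(cfg: dict) -> StudentParams:
    return StudentParams.from_dict(cfg["student"])


def parse_curriculum(cfg: dict) -> CurriculumSpec:
    return CurriculumSpec.from_dict(cfg.get("curriculum", {}))


def parse_continuous(cfg: dict) -> ContinuousSpec:
    return ContinuousSpec(**cfg.get("continuous", {}))


def load_policy(path: str | Path):
    """Load an ADP policy (discrete or continuous, inferred from keys)."""
    d = load_config(path)
    if "theta_hi" in d:
        return ContAdpPolicy.from_dict(d)
    return ADPPolicy.from_dict(d)


def save_policy(policy, path: str | Path) -> None:
    save_config(policy.to_dict(), Path(path))
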
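"""Teacher-observable transcript and success-rate features.

The teacher never sees the student's action values: its only observable is
the transcript of (level, outcome) pairs.  Teachers that act on success
rates use an exponential moving average (EMA) estimate ``s_hat`` per level
and its per-interaction change ``delta_s_hat``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Transcript", "RateTracker", "ema_update"]


def ema_update(s: float, x: float, beta: float) -> float:
    """One EMA step: ``(1 - beta) * s + beta * x`` with x a binary outcome."""
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must be in [0, 1]")
    if x not in (0, 1, 0.0, 1.0):
        raise ValueError("x must be a binary outcome")
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must be in (0, 1)")
    return (1.0 - beta) * s + beta * float(x)


@dataclass
class TranscriptEntry:
    t: int
    level: float
    outcomes: list
    s_hat: float
    delta_s_hat: float
    action: str = ""


@dataclass
class Transcript:
    """Ordered record of interactions; serialisable to JSONL, one record each."""

    entries: list = field(default_factory=list)

    def append(self, entry: TranscriptEntry) -> None:
        if self.entries and entry.t <= self.entries[-1].t:
            raise ValueError("interaction indices must be strictly increasing")
        self.entries.append(entry)

    def to_jsonl(self) -> str:
        lines = []
        for e in self.entries:
            lines.append(
                json.dumps(
                    {
                        "t": e.t,
                        "level": e.level,
                        "outcomes": [int(x) for x in e.outcomes],
                        "s_hat": e.s_hat,
                        "delta_s_hat": e.delta_s_hat,
                        "action": e.action,
                    }
                )
            )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str) -> "Transcript":
        tr = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            tr.append(
                TranscriptEntry(
                    t=d["t"],
                    level=d["level"],
                    outcomes=d["outcomes"],
                    s_hat=d["s_hat"],
                    delta_s_hat=d["delta_s_hat"],
                    action=d.get("action", ""),
                )
            )
        return tr


class RateTracker:
    """Per-level EMA success-rate estimates.

    Each difficulty level keeps its own EMA, initialised to 0 on first
    visit and persisting across level changes — revisiting a level resumes
    its estimate, so a teacher that drops back remembers the student's
    competence there.
    """

    def __init__(self, beta: float = 0.1):
        if not (0.0 < beta < 1.0):
            raise ValueError("beta must be in (0, 1)")
        self.beta = beta
        self._s: dict = {}

    @staticmethod
    def _key(level) -> float:
        return round(float(level), 9)

    def value(self, level) -> float:
        """Current estimate for ``level`` (0 if never visited)."""
        return self._s.get(self._key(level), 0.0)

    def levels(self) -> list:
        return sorted(self._s)

    def observe(self, level, outcomes) -> tuple[float, float]:
        """Fold one interaction block into the level's EMA.

        Returns ``(s_hat, delta_s_hat)`` where ``delta_s_hat`` is the change
        over this block.  Other levels' estimates are untouched.
        """
        outcomes = np.asarray(outcomes)
        if outcomes.size == 0:
            raise ValueError("outcome block must be nonempty")
        key = self._key(level)
        before = self._s.get(key, 0.0)
        s = before
        for x in outcomes:
            s = ema_update(s, int(x), self.beta)
        self._s[key] = s
        return s, s - before

    def copy(self) -> "RateTracker":
        t = RateTracker(self.beta)
        t._s = dict(self._s)
        return t
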
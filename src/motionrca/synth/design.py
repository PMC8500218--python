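"""Experimental session design for the two global-motion tasks.

Two random-dot-kinematogram tasks are emulated:

* **motion coherence** — a fraction of dots share the trial direction
  (easy 75%, difficult 30%, catch 100%);
* **direction integration** — every dot direction is drawn from a
  Gaussian around the trial direction (easy SD 30 deg, difficult
  SD 70 deg, catch SD 0).

A session contains 72 trials per non-catch difficulty level (half
leftward, half rightward) plus 8 randomly interleaved catch trials,
arranged in 4 blocks of 38.  Each trial has jittered fixation
(800-1000 ms), random-motion (800-1000 ms) and offset (200-400 ms)
periods; the stimulus period ends at the response or after 2500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

TASKS = ("coherence", "integration")

#: difficulty level values: coherence % or direction SD in degrees
LEVELS = {
    "coherence": {"easy": 75.0, "difficult": 30.0, "catch": 100.0},
    "integration": {"easy": 30.0, "difficult": 70.0, "catch": 0.0},
}

MAX_STIMULUS_MS = 2500.0


@dataclass
class StimulusParams:
    """Dot-field and trial-timing parameters."""

    n_dots: int = 100
    dot_diameter_deg: float = 0.19
    speed_deg_s: float = 6.0
    field_size_deg: float = 10.0
    lifetime_ms: float = 400.0
    fixation_range_ms: tuple[float, float] = (800.0, 1000.0)
    random_motion_range_ms: tuple[float, float] = (800.0, 1000.0)
    max_stimulus_ms: float = MAX_STIMULUS_MS
    offset_range_ms: tuple[float, float] = (200.0, 400.0)
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("fixation_range_ms", "random_motion_range_ms", "offset_range_ms"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range {name}={lo, hi}")
        if min(self.n_dots, self.speed_deg_s, self.field_size_deg,
               self.lifetime_ms, self.max_stimulus_ms, self.frame_rate_hz) <= 0:
            raise ValueError("stimulus parameters must be positive")

    @property
    def lifetime_frames(self) -> int:
        return int(round(self.lifetime_ms / 1000.0 * self.frame_rate_hz))


@dataclass
class TrialRecord:
    """One behavioural trial."""

    task: str
    difficulty: str           # easy | difficult | catch
    level: float              # coherence % or direction SD (deg)
    direction: str            # left | right
    fixation_ms: float
    random_ms: float
    offset_ms: float
    block: int = 0
    response: str = "none"    # left | right | none
    rt_ms: float | None = None
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.difficulty not in ("easy", "difficult", "catch"):
            raise ValueError(f"unknown difficulty {self.difficulty!r}")
        if self.direction not in ("left", "right"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if (self.rt_ms is not None) != (self.response != "none"):
            raise ValueError("rt present iff a response was made")
        if self.rt_ms is not None and self.rt_ms > MAX_STIMULUS_MS:
            raise ValueError("rt exceeds the maximum stimulus duration")


@dataclass
class SessionPlan:
    task: str
    trials: list[TrialRecord] = field(default_factory=list)
    blocks: int = 4
    trials_per_block: int = 38

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.difficulty] = out.get(t.difficulty, 0) + 1
        return out

    def validate(self) -> None:
        if self.blocks * self.trials_per_block != self.n_trials:
            raise ValueError("blocks x trials_per_block != total trials")
        for diff in ("easy", "difficult", "catch"):
            dirs = [t.direction for t in self.trials if t.difficulty == diff]
            if dirs.count("left") != dirs.count("right"):
                raise ValueError(f"direction imbalance in {diff!r} trials")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.trials])


def make_session_plan(
    task: str,
    params: StimulusParams | None = None,
    seed: int = 0,
    n_per_level: int = 72,
    n_catch: int = 8,
    blocks: int = 4,
) -> SessionPlan:
    """Build a seeded session plan with balanced, randomly interleaved trials.

    Defaults reproduce the full design (72 easy + 72 difficult + 8 catch
    trials in 4 blocks of 38); smaller balanced designs can be requested
    for quick simulations.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if n_per_level % 2 or n_catch % 2:
        raise ValueError("trial counts per level must be even for L/R balance")
    total = 2 * n_per_level + n_catch
    if total % blocks:
        raise ValueError("total trial count must divide evenly into blocks")
    params = params or StimulusParams()
    rng = np.random.default_rng(seed)

    proto: list[tuple[str, str]] = []
    for diff, n in (("easy", n_per_level), ("difficult", n_per_level), ("catch", n_catch)):
        proto += [(diff, "left")] * (n // 2) + [(diff, "right")] * (n // 2)
    order = rng.permutation(len(proto))

    trials = []
    per_block = total // blocks
    for pos, j in enumerate(order):
        diff, direction = proto[j]
        trials.append(
            TrialRecord(
                task=task,
                difficulty=diff,
                level=LEVELS[task][diff],
                direction=direction,
                fixation_ms=float(rng.uniform(*params.fixation_range_ms)),
                random_ms=float(rng.uniform(*params.random_motion_range_ms)),
                offset_ms=float(rng.uniform(*params.offset_range_ms)),
                block=pos // per_block,
            )
        )
    plan = SessionPlan(task=task, trials=trials, blocks=blocks, trials_per_block=per_block)
    plan.validate()
    return plan


def plan_from_frame(df: pd.DataFrame, blocks: int | None = None) -> SessionPlan:
    """Rebuild a :class:`SessionPlan` from its CSV/DataFrame form."""
    trials = []
    for _, row in df.iterrows():
        rt = row.get("rt_ms")
        rt = None if rt is None or (isinstance(rt, float) and np.isnan(rt)) else float(rt)
        correct = row.get("correct")
        if correct is not None and isinstance(correct, float) and np.isnan(correct):
            correct = None
        trials.append(
            TrialRecord(
                task=row["task"], difficulty=row["difficulty"], level=float(row["level"]),
                direction=row["direction"], fixation_ms=float(row["fixation_ms"]),
                random_ms=float(row["random_ms"]), offset_ms=float(row["offset_ms"]),
                block=int(row.get("block", 0)), response=row.get("response", "none"),
                rt_ms=rt, correct=None if correct is None else bool(correct),
            )
        )
    task = trials[0].task
    blocks = blocks or (max(t.block for t in trials) + 1)
    return SessionPlan(task=task, trials=trials, blocks=blocks,
                       trials_per_block=len(trials) // blocks)
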
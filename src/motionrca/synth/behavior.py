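"""Simulated behavioural responses.

The analysis package never models behaviour; the generator only needs
responses with the qualitative structure the downstream statistics
assume: accuracy is Bernoulli per condition, response time is log-normal
per condition, and responses slower than the 2500 ms stimulus limit are
recorded as timeouts (no response, no RT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import MAX_STIMULUS_MS, SessionPlan


@dataclass
class BehaviorModel:
    """Per-difficulty accuracy and log-normal RT parameters.

    ``rt_median_ms`` is the log-normal median (exp of the log-scale
    location); ``rt_sigma`` the log-scale SD, shared across conditions.
    """

    accuracy: dict[str, float] = field(
        default_factory=lambda: {"easy": 0.92, "difficult": 0.82, "catch": 0.97}
    )
    rt_median_ms: dict[str, float] = field(
        default_factory=lambda: {"easy": 900.0, "difficult": 1250.0, "catch": 800.0}
    )
    rt_sigma: float = 0.35
    lapse_timeout_p: float = 0.01   # extra chance of simply not responding

    def __post_init__(self) -> None:
        for d, p in self.accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy[{d!r}] outside [0, 1]")
        if not 0.0 <= self.lapse_timeout_p <= 1.0:
            raise ValueError("lapse_timeout_p outside [0, 1]")

    @classmethod
    def for_task(cls, task: str) -> "BehaviorModel":
        if task == "integration":
            return cls(accuracy={"easy": 0.93, "difficult": 0.78, "catch": 0.97},
                       rt_median_ms={"easy": 950.0, "difficult": 1200.0, "catch": 800.0})
        return cls()


def simulate_behavior(plan: SessionPlan, model: BehaviorModel | None = None,
                      seed: int = 0) -> SessionPlan:
    """Fill responses, RTs and correctness into a copy of ``plan``.

    RTs are drawn from the per-condition log-normal; draws exceeding the
    2500 ms stimulus limit become timeouts (response ``"none"``).
    """
    model = model or BehaviorModel()
    rng = np.random.default_rng(seed)
    out = []
    for t in plan.trials:
        rt = float(rng.lognormal(np.log(model.rt_median_ms[t.difficulty]), model.rt_sigma))
        timeout = rt > MAX_STIMULUS_MS or rng.random() < model.lapse_timeout_p
        if timeout:
            out.append(replace(t, response="none", rt_ms=None, correct=None))
            continue
        hit = rng.random() < model.accuracy[t.difficulty]
        resp = t.direction if hit else ("left" if t.direction == "right" else "right")
        out.append(replace(t, response=resp, rt_ms=rt, correct=bool(resp == t.direction)))
    return SessionPlan(task=plan.task, trials=out, blocks=plan.blocks,
                       trials_per_block=plan.trials_per_block)
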
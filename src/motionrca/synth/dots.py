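"""Frame-by-frame random-dot-kinematogram simulation.

Dots live in a square field with wrap-around, limited lifetime (respawn
at a random position when it expires, starting lifetimes randomized) and
move at a fixed speed.  Direction assignment depends on the task:

* coherence: ``round(coherence/100 * n_dots)`` dots move in the trial
  direction each frame, the rest move in uniformly random directions.
  By default the coherent subset is re-drawn every frame (the
  "different-dot" rule); ``coherent_rule="same"`` keeps the subset fixed.
* integration: each dot's direction is drawn from a Gaussian centred on
  the trial direction with the level's SD.  By default a dot keeps its
  direction for its lifetime (``redraw="birth"``); ``redraw="frame"``
  re-samples every frame.

Angles are in degrees; 0 = rightward, 180 = leftward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StimulusParams, TrialRecord


@dataclass
class DotFrames:
    positions: np.ndarray    # (n_frames, n_dots, 2) deg
    directions: np.ndarray   # (n_frames, n_dots) deg
    coherent: np.ndarray     # (n_frames, n_dots) bool (all True for integration)


def _trial_angle(direction: str) -> float:
    return 0.0 if direction == "right" else 180.0


def simulate_dot_frames(
    trial: TrialRecord,
    params: StimulusParams | None = None,
    n_frames: int = 60,
    seed: int = 0,
    coherent_rule: str = "different",
    redraw: str = "birth",
) -> DotFrames:
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    params = params or StimulusParams()
    if trial.task == "coherence" and not (0.0 <= trial.level <= 100.0):
        raise ValueError("coherence outside [0, 100]")
    if trial.task == "integration" and trial.level < 0:
        raise ValueError("negative direction SD")
    if coherent_rule not in ("different", "same"):
        raise ValueError("coherent_rule must be 'different' or 'same'")
    if redraw not in ("birth", "frame"):
        raise ValueError("redraw must be 'birth' or 'frame'")

    rng = np.random.default_rng(seed)
    n = params.n_dots
    size = params.field_size_deg
    step = params.speed_deg_s / params.frame_rate_hz
    life_max = params.lifetime_frames
    mean_angle = _trial_angle(trial.direction)

    pos = rng.uniform(0.0, size, size=(n, 2))
    lifetime = rng.integers(0, life_max, size=n)  # randomized starting lifetimes

    if trial.task == "coherence":
        n_coh = int(round(trial.level / 100.0 * n))
        coherent_idx = rng.permutation(n)[:n_coh]
    else:
        dirs = rng.normal(mean_angle, trial.level, size=n)

    positions = np.empty((n_frames, n, 2))
    directions = np.empty((n_frames, n))
    coherent = np.zeros((n_frames, n), dtype=bool)

    for f in range(n_frames):
        # respawn expired dots at random positions with fresh directions
        expired = lifetime >= life_max
        if expired.any():
            pos[expired] = rng.uniform(0.0, size, size=(int(expired.sum()), 2))
            lifetime[expired] = 0
            if trial.task == "integration":
                dirs[expired] = rng.normal(mean_angle, trial.level, size=int(expired.sum()))

        if trial.task == "coherence":
            if coherent_rule == "different":
                coherent_idx = rng.permutation(n)[: int(round(trial.level / 100.0 * n))]
            frame_dirs = rng.uniform(0.0, 360.0, size=n)
            frame_dirs[coherent_idx] = mean_angle
            coherent[f, coherent_idx] = True
        else:
            if redraw == "frame":
                dirs = rng.normal(mean_angle, trial.level, size=n)
            frame_dirs = dirs.copy()
            coherent[f] = True

        positions[f] = pos
        directions[f] = frame_dirs

        rad = np.deg2rad(frame_dirs)
        pos = (pos + step * np.column_stack([np.cos(rad), np.sin(rad)])) % size
        lifetime += 1

    return DotFrames(positions=positions, directions=directions, coherent=coherent)
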
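"""Stage-wise nest decay under a temporally autocorrelated seasonal factor.

Every nest carries its own expected sojourn time (in days) for each of the
five decay stages A-E. On each day a nest in stage ``s`` advances to the
next stage with probability ``clamp(seasonal_factor / duration[s], 0, 1)``
-- a geometric sojourn whose mean equals the duration when the factor is 1.
A nest leaving stage E has disappeared. One seasonal factor is shared by
the whole grid per day; it performs a Gaussian random walk (daily increment
Normal(0, 0.05)) clamped to [0.625, 1.6], so the realised daily hazards can
vary by up to a factor of 1.6 / 0.625 = 2.56 over time.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .agents import NestArena
from .config import SimConfig


@dataclasses.dataclass
class SeasonalState:
    """Current value (and optional history) of the seasonal decay factor."""

    factor: float = 1.0
    day: int = 0
    keep_history: bool = False
    history: list = dataclasses.field(default_factory=list)


def update_seasonal(state: SeasonalState, config: SimConfig,
                    rng: np.random.Generator) -> float:
    """Advance the seasonal random walk one day; returns the new factor."""
    lo, hi = config.seasonal_bounds
    increment = rng.normal(0.0, config.seasonal_increment_scale)
    factor = min(max(state.factor + increment, lo), hi)
    state.factor = factor
    state.day += 1
    if state.keep_history:
        state.history.append(factor)
    return factor


def daily_decay(arena: NestArena, seasonal_factor: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Advance every live nest by at most one stage.

    Returns ``(advanced, died)`` arena indices; ``died`` nests decayed past
    stage E and are removed from the standing crop.
    """
    live = arena.live_indices()
    if live.size == 0:
        return live, live
    dur = arena.durations[live, arena.stage[live]]
    p = np.clip(seasonal_factor / dur, 0.0, 1.0)
    advanced = live[rng.random(live.size) < p]
    arena.stage[advanced] += 1
    died = advanced[arena.stage[advanced] >= arena.durations.shape[1]]
    if died.size:
        arena.mark_dead(died)
    return advanced, died


def simulate_lifetimes(durations: np.ndarray, rng: np.random.Generator,
                       seasonal_factor: float = 1.0) -> np.ndarray:
    """Total days from construction to disappearance for a nest cohort.

    Runs the actual daily mechanism (one shared arena, constant seasonal
    factor) rather than a closed form, so it exercises the same code path
    as a full simulation. ``durations`` has shape ``(n, 5)``.
    """
    durations = np.asarray(durations, dtype=np.float32)
    n = len(durations)
    arena = NestArena(grid_side=max(n, 2))
    # park each nest on its own square so no replacement can occur
    arena.add(np.arange(n), np.zeros(n, dtype=int), 0, 0, durations)
    death_day = np.zeros(n, dtype=np.int64)
    day = 0
    while arena.n_live() > 0:
        day += 1
        _, died = daily_decay(arena, seasonal_factor, rng)
        death_day[died] = day
    return death_day
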
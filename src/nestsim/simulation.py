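"""Day-loop engine tying together world, agents, decay and surveys.

Order of events within a simulated day: the seasonal factor advances one
random-walk step, every live nest gets its daily chance to decay, then the
orangutans move and build their nests (so a nest built today is observed
fresh in stage A on a same-day survey and takes its first decay step the
following day).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import agents, decay, survey
from .agents import NestArena
from .config import SimConfig
from .decay import SeasonalState
from .survey import Transect
from .world import Environment, init_environment

#: compact the nest arena whenever dead rows outnumber live ones this much
_COMPACT_DEAD_RATIO = 1.0
_COMPACT_MIN_ROWS = 200_000


class Simulation:
    """A single simulation run: one environment, one moving population.

    Parameters
    ----------
    config
        Validated simulation configuration.
    seed
        Seed for the run's random stream; overrides ``config.seed``.
    rng
        Alternatively, an existing :class:`numpy.random.Generator`.
    """

    def __init__(self, config: SimConfig, seed: int | None = None,
                 rng: np.random.Generator | None = None):
        config.validate()
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed if seed is None else seed)
        self.rng = rng
        self.env: Environment = init_environment(config, rng)
        self.positions = agents.init_orangutans(config, rng)
        self.arena = NestArena(config.grid_side)
        self.seasonal = SeasonalState()
        self.day = 0
        self._obs_rows: list[tuple] = []
        self._n_surveys = 0

    # -- dynamics ---------------------------------------------------------
    def step(self) -> None:
        """Advance the simulation by one day."""
        self.day += 1
        factor = decay.update_seasonal(self.seasonal, self.config, self.rng)
        decay.daily_decay(self.arena, factor, self.rng)
        if len(self.positions):
            new_pos, steps, dirs = agents.move_all(self.positions, self.config,
                                                   self.rng)
            agents.build_nests(self.arena, self.env, self.day, self.positions,
                               new_pos, steps, dirs, self.rng)
            self.positions = new_pos
        a = self.arena
        if a.n > _COMPACT_MIN_ROWS and a.n - a.n_live() > a.n_live() * _COMPACT_DEAD_RATIO:
            a.compact()

    def run_until(self, day: int) -> None:
        while self.day < day:
            self.step()

    def remove_fraction(self, fraction: float) -> int:
        """Remove a fraction of the population; returns the new head count."""
        self.positions = agents.remove_fraction(self.positions, fraction, self.rng)
        return len(self.positions)

    # -- surveying --------------------------------------------------------
    def run_survey(self, transects: Sequence[Transect], visibility: str) -> int:
        """Survey all transects today; appends rows to the run's table."""
        self._n_surveys += 1
        rows = survey.run_survey(self.arena, transects, visibility, self.config,
                                 self.rng, survey_index=self._n_surveys,
                                 day=self.day)
        self._obs_rows.extend(rows)
        return len(rows)

    def observations(self) -> pd.DataFrame:
        return survey.observations_to_frame(self._obs_rows)


def run_survey_series(config: SimConfig, n_transects: int,
                      transect_length: int, n_surveys: int, visibility: str,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      removal_days: dict[int, float] | None = None,
                      ) -> tuple[pd.DataFrame, list[Transect], Simulation]:
    """Run a complete survey campaign and return its observation table.

    Burns in to ``config.first_survey_day`` and then surveys every
    ``survey_interval_days`` for ``n_surveys`` surveys along one fixed set
    of transects. ``removal_days`` optionally maps day -> fraction of the
    remaining population removed at the start of that day (population
    decline scenarios).
    """
    sim = Simulation(config, seed=seed, rng=rng)
    transects = survey.place_transects(n_transects, transect_length, config,
                                       sim.rng)
    survey_days = [config.first_survey_day + k * config.survey_interval_days
                   for k in range(n_surveys)]
    removal_days = removal_days or {}
    last_day = survey_days[-1]
    survey_set = set(survey_days)
    for day in range(sim.day + 1, last_day + 1):
        if day in removal_days:
            sim.remove_fraction(removal_days[day])
        sim.step()
        if day in survey_set:
            sim.run_survey(transects, visibility)
    return sim.observations(), transects, sim
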
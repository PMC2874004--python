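"""Deterministic observation-table fixtures and scaled-down worlds.

The fixture generator builds schema-valid observation tables from explicit
per-nest stage trajectories, together with the ground-truth quantities an
estimator should recover from them (transition counts, marked-recount new
nest count, per-survey standing counts). This lets the estimators and the
experiment plumbing be tested in milliseconds without running a simulation.

:func:`make_micro_world` scales the default 100 km^2 world down while
preserving the orangutan density (2/km^2) and all per-day rates, so that
integration tests exercise the full mechanism at a fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .config import N_STAGES, STAGES, SimConfig
from .errors import FixtureError
from .estimators import DISAPPEARED
from .survey import observations_to_frame


@dataclasses.dataclass
class Trajectory:
    """A group of nests sharing one stage history.

    ``stages`` lists the observed stage at consecutive surveys starting at
    ``first_survey`` (1-based); after the last listed stage the nest has
    disappeared (if surveys remain) -- e.g. ``("A", "B")`` first seen at
    survey 1 of a 3-survey table decays completely before survey 3.
    """

    count: int
    stages: tuple[str, ...]
    first_survey: int = 1
    klass: str = "night"


@dataclasses.dataclass
class FixtureSpec:
    """Specification of a deterministic observation-table fixture."""

    n_surveys: int
    trajectories: tuple[Trajectory, ...]
    first_day: int = 1000
    interval_days: int = 30
    seed: int = 0

    def validate(self) -> "FixtureSpec":
        if self.n_surveys < 1:
            raise FixtureError("n_surveys must be >= 1")
        if not self.trajectories:
            raise FixtureError("at least one trajectory is required")
        order = {s: i for i, s in enumerate(STAGES)}
        for t in self.trajectories:
            if t.count < 1:
                raise FixtureError("trajectory count must be >= 1")
            if not t.stages:
                raise FixtureError("trajectory must list at least one stage")
            bad = [s for s in t.stages if s not in order]
            if bad:
                raise FixtureError(f"unknown stage {bad[0]!r}")
            idx = [order[s] for s in t.stages]
            if any(b < a for a, b in zip(idx, idx[1:])):
                raise FixtureError(
                    f"stages must be non-decreasing, got {t.stages}")
            if t.first_survey < 1 or (t.first_survey + len(t.stages) - 1
                                      > self.n_surveys):
                raise FixtureError(
                    f"trajectory {t.stages} does not fit in {self.n_surveys} "
                    "surveys")
        return self


def make_observation_fixture(spec: FixtureSpec
                             ) -> tuple[pd.DataFrame, dict]:
    """Emit a schema-valid observation table with known ground truth.

    Returns ``(observations, expected)`` where ``expected`` holds the
    stage-transition count matrix (5 x 6, last column = disappeared), the
    marked-recount new-nest count (first detections on surveys >= 2) and
    the per-survey standing counts implied by the trajectories. The output
    is a pure function of the spec, so identical specs give byte-identical
    CSV files.
    """
    spec.validate()
    stage_of = {s: i for i, s in enumerate(STAGES)}
    rows = []
    counts = np.zeros((N_STAGES, N_STAGES + 1), dtype=np.int64)
    marked_new = 0
    per_survey = np.zeros(spec.n_surveys, dtype=np.int64)
    nest_id = 0
    for traj in spec.trajectories:
        for _ in range(traj.count):
            for j, stage in enumerate(traj.stages):
                k = traj.first_survey + j
                day = spec.first_day + (k - 1) * spec.interval_days
                first = int(j == 0)
                rows.append((k, day, 0, nest_id, stage, first, traj.klass))
                per_survey[k - 1] += 1
            if traj.first_survey >= 2:
                marked_new += 1
            idx = [stage_of[s] for s in traj.stages]
            for a, b in zip(idx, idx[1:]):
                counts[a, b] += 1
            last_survey = traj.first_survey + len(traj.stages) - 1
            if last_survey < spec.n_surveys:
                counts[idx[-1], DISAPPEARED] += 1
            nest_id += 1
    obs = observations_to_frame(rows).sort_values(
        ["survey_index", "nest_id"], kind="stable").reset_index(drop=True)
    expected = {
        "transition_counts": counts,
        "marked_new_nests": marked_new,
        "per_survey_counts": per_survey,
        "n_nests": nest_id,
    }
    return obs, expected


def make_micro_world(config: SimConfig | None = None, grid_side: int = 2500,
                     first_survey_day: int = 800,
                     preserve_density: bool = True,
                     **overrides) -> SimConfig:
    """A smaller world with the same densities and per-day rates.

    Shrinks only the area, the population (kept at the base density,
    2/km^2 by default) and the burn-in; every rate parameter is inherited
    unchanged. Warns when the burn-in is shorter than three mean nest
    lifetimes, since the standing crop may then not have equilibrated.
    """
    base = (config or SimConfig()).validate()
    kwargs: dict = dict(grid_side=grid_side, first_survey_day=first_survey_day)
    if preserve_density and "n_orangutans" not in overrides:
        area_ratio = (grid_side / base.grid_side) ** 2
        kwargs["n_orangutans"] = int(round(base.n_orangutans * area_ratio))
    kwargs.update(overrides)
    micro = base.replace(**kwargs)
    mean_lifetime = sum(micro.stage_mean_days)
    if micro.first_survey_day < 3 * mean_lifetime:
        warnings.warn(
            f"burn-in of {micro.first_survey_day} days is shorter than three "
            f"mean nest lifetimes ({3 * mean_lifetime:.0f} days); the "
            "standing crop may not be at equilibrium", stacklevel=2)
    return micro
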
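"""Simulation configuration.

All tunable parameters of the simulated world live in :class:`SimConfig`.
Defaults describe a 10 km x 10 km forest block (5000 x 5000 squares of
2 m x 2 m) holding 200 nest-building orangutans (2 individuals/km^2), with
five ordinal nest decay stages (A-E) whose mean sojourn times sum to 265
days, stage-specific detection probabilities for survey teams, and a
temporally autocorrelated seasonal decay factor bounded in [0.625, 1.6].
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .errors import ConfigurationError

#: durations drawn from normal distributions are floored here so that the
#: daily transition hazard stays finite
MIN_DURATION_DAYS = 0.5

#: number of ordinal decay stages (A..E)
N_STAGES = 5

STAGES = "ABCDE"


@dataclasses.dataclass
class SimConfig:
    """Full parameterization of the simulated world and surveys.

    Lengths are in grid squares unless a field name says metres; one square
    is ``square_size`` metres on a side (2 m by default, so the default grid
    spans 10 km and 100 km^2).
    """

    grid_side: int = 5000
    square_size: float = 2.0
    n_tree_types: int = 4
    stage_mean_days: tuple[float, ...] = (5.0, 20.0, 40.0, 80.0, 120.0)
    stage_spread_days: tuple[float, ...] = (2.5, 10.0, 20.0, 40.0, 60.0)
    altitude_slope: float = 0.3
    seasonal_increment_scale: float = 0.05
    seasonal_bounds: tuple[float, float] = (0.625, 1.6)
    move_mean_squares: float = 350.0
    move_spread_squares: float = 100.0
    day_nest_rate: float = 0.2
    day_nest_factor: float = 1.667
    nest_build_rate_r: float = 1.2
    n_orangutans: int = 200
    survey_interval_days: int = 30
    strip_width_squares: int = 10
    first_survey_day: int = 1000
    detect_prob_by_stage: tuple[float, ...] = (0.9, 0.95, 0.95, 0.85, 0.8)
    complete_visibility_prob: float = 0.99
    correction_factor: float = 0.89
    seed: int | None = None

    # -- derived geometry -------------------------------------------------
    @property
    def x_mid(self) -> float:
        """Midpoint of the x axis; the altitudinal multiplier is 1 there."""
        return (self.grid_side - 1) / 2.0

    @property
    def span_m(self) -> float:
        """Side length of the simulated area in metres."""
        return self.grid_side * self.square_size

    @property
    def area_m2(self) -> float:
        """Total simulated area in square metres (1e8 under defaults)."""
        return self.span_m ** 2

    @property
    def strip_width_m(self) -> float:
        return self.strip_width_squares * self.square_size

    @property
    def true_density_per_m2(self) -> float:
        return self.n_orangutans / self.area_m2

    # -- validation -------------------------------------------------------
    def validate(self) -> "SimConfig":
        def fail(field: str, why: str):
            raise ConfigurationError(f"invalid config field '{field}': {why}")

        if self.grid_side < 2:
            fail("grid_side", "must be >= 2")
        if self.square_size <= 0:
            fail("square_size", "must be > 0")
        if self.n_tree_types < 1:
            fail("n_tree_types", "must be >= 1")
        if len(self.stage_mean_days) != N_STAGES:
            fail("stage_mean_days", f"must have {N_STAGES} entries")
        if len(self.stage_spread_days) != N_STAGES:
            fail("stage_spread_days", f"must have {N_STAGES} entries")
        if any(d <= 0 for d in self.stage_mean_days):
            fail("stage_mean_days", "durations must be > 0")
        if any(s < 0 for s in self.stage_spread_days):
            fail("stage_spread_days", "spreads must be >= 0")
        lo, hi = self.seasonal_bounds
        if not (lo < 1.0 < hi):
            fail("seasonal_bounds", "must bracket 1.0")
        if self.seasonal_increment_scale < 0:
            fail("seasonal_increment_scale", "must be >= 0")
        if self.move_mean_squares < 0 or self.move_spread_squares < 0:
            fail("move_mean_squares", "movement parameters must be >= 0")
        if not (0.0 <= self.day_nest_rate <= 1.0):
            fail("day_nest_rate", "must be a probability in [0, 1]")
        if self.day_nest_factor <= 0:
            fail("day_nest_factor", "must be > 0")
        if self.nest_build_rate_r <= 0:
            fail("nest_build_rate_r", "must be > 0")
        if self.n_orangutans < 0:
            fail("n_orangutans", "must be >= 0")
        if self.survey_interval_days <= 0:
            fail("survey_interval_days", "must be > 0")
        if not (1 <= self.strip_width_squares <= self.grid_side):
            fail("strip_width_squares", "must fit inside the grid")
        if self.first_survey_day < 1:
            fail("first_survey_day", "must be >= 1")
        if len(self.detect_prob_by_stage) != N_STAGES:
            fail("detect_prob_by_stage", f"must have {N_STAGES} entries")
        if any(not (0.0 <= p <= 1.0) for p in self.detect_prob_by_stage):
            fail("detect_prob_by_stage", "entries must be probabilities")
        if not (0.0 <= self.complete_visibility_prob <= 1.0):
            fail("complete_visibility_prob", "must be a probability")
        if self.correction_factor <= 0:
            fail("correction_factor", "must be > 0")
        return self

    def replace(self, **overrides: Any) -> "SimConfig":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **overrides).validate()

    # -- flat key/value (YAML) round trip ---------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigurationError(
                f"invalid config field '{sorted(unknown)[0]}': unknown field"
            )
        kwargs = {}
        for k, v in data.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
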
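"""Static simulation environment: trees, altitude gradient, decay-time means.

Each grid square holds exactly one tree, its type drawn equiprobably from
``n_tree_types`` types. For every tree type the mean sojourn time of each
decay stage is itself drawn from a normal hyper-distribution (population-level
means 5, 20, 40, 80, 120 days with spreads equal to half the means), so the
stage structure differs between runs the way it differs between field sites.
An altitudinal gradient along the x axis rescales all decay times linearly:
nests at higher x (higher altitude) persist longer.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import MIN_DURATION_DAYS, N_STAGES, SimConfig
from .errors import BoundsError


def altitude_multiplier(x, config: SimConfig):
    """Altitudinal decay-time multiplier m(x) = 1 + slope * (x - x_mid) / x_mid.

    The multiplier is 1 at the centre of the x axis, 1 - slope at x = 0 and
    approximately 1 + slope at the far edge; it is clamped to stay positive.
    Accepts a scalar or an array of square x coordinates.

    Raises
    ------
    BoundsError
        If any coordinate lies outside ``[0, grid_side)``.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa >= config.grid_side):
        raise BoundsError(f"x coordinate out of grid [0, {config.grid_side})")
    m = 1.0 + config.altitude_slope * (xa - config.x_mid) / config.x_mid
    m = np.maximum(m, 1e-3)
    if np.isscalar(x):
        return float(m)
    return m


@dataclasses.dataclass
class Environment:
    """The immutable world a single simulation run takes place in.

    Attributes
    ----------
    tree_type : (grid_side, grid_side) int8 array
        Tree type index of each square, indexed ``[x, y]``.
    type_stage_mean : (n_tree_types, 5) float array
        Mean decay-stage sojourn time in days for each tree type and stage.
    alt_by_x : (grid_side,) float array
        Precomputed altitudinal multiplier per x coordinate.
    """

    tree_type: np.ndarray
    type_stage_mean: np.ndarray
    alt_by_x: np.ndarray
    config: SimConfig

    def stage_means_at(self, x, y) -> np.ndarray:
        """Per-stage mean durations of the trees at squares ``(x, y)``."""
        return self.type_stage_mean[self.tree_type[x, y]]


def init_environment(config: SimConfig, rng: np.random.Generator) -> Environment:
    """Draw a fresh environment: tree layout and per-type stage means.

    Per-type stage means are drawn from ``Normal(stage_mean_days[s],
    stage_spread_days[s])`` and floored at ``MIN_DURATION_DAYS``. The spread
    used later for per-nest draws is half the per-type mean.
    """
    config.validate()
    g = config.grid_side
    tree_type = rng.integers(0, config.n_tree_types, size=(g, g), dtype=np.int8)
    means = rng.normal(
        loc=np.asarray(config.stage_mean_days, dtype=float),
        scale=np.asarray(config.stage_spread_days, dtype=float),
        size=(config.n_tree_types, N_STAGES),
    )
    means = np.maximum(means, MIN_DURATION_DAYS)
    alt = altitude_multiplier(np.arange(g), config)
    return Environment(tree_type=tree_type, type_stage_mean=means,
                       alt_by_x=alt, config=config)
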
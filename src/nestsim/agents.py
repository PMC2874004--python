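"""Orangutan movement and nest construction.

Each simulated day every orangutan takes one net displacement: a step count
drawn from Normal(350, 100) squares (700 +/- 200 m), rounded and floored at
zero, in one of the eight compass directions chosen uniformly. At a grid
edge the direction set is restricted to directions pointing away from the
edge (reflecting boundary) and any overshoot reflects off the wall.
Distance is counted in squares traversed, so diagonal moves cover the same
number of squares as cardinal ones.

The boundary is reflecting in both senses: the direction set is restricted
at the edge, and any overshoot past the wall is folded back into the grid
(a bounce), so no probability mass piles up on the boundary squares.

After moving, the orangutan always builds a night nest at its end-of-day
position and, with probability ``day_nest_rate`` (0.2), one day nest at a
uniformly random square along the day's path. Day nests are identical to
night nests except that every stage duration is divided by the day-nest
factor (1.667), so they decay 1.667x faster. A nest built on a square that
already holds a live nest *replaces* it: the old nest is removed and the
new one starts fresh and untagged.
"""

from __future__ import annotations

import numpy as np

from .config import MIN_DURATION_DAYS, N_STAGES, SimConfig
from .errors import ParameterError
from .world import Environment

#: the eight compass directions as (dx, dy) unit steps, E first, anticlockwise
DIR_VECTORS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)
DIR_NAMES = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")

NIGHT, DAY = 0, 1
KLASS_NAMES = ("night", "day")


def init_orangutans(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random initial positions, shape ``(n_orangutans, 2)``."""
    return rng.integers(0, config.grid_side, size=(config.n_orangutans, 2),
                        dtype=np.int64)


def _allowed_directions(x: int, y: int, grid_side: int) -> np.ndarray:
    """Direction indices that do not point off-grid from an edge square."""
    ok = np.ones(8, dtype=bool)
    if x == 0:
        ok &= DIR_VECTORS[:, 0] >= 0
    if x == grid_side - 1:
        ok &= DIR_VECTORS[:, 0] <= 0
    if y == 0:
        ok &= DIR_VECTORS[:, 1] >= 0
    if y == grid_side - 1:
        ok &= DIR_VECTORS[:, 1] <= 0
    return np.flatnonzero(ok)


def reflect_coordinate(coord, grid_side: int):
    """Fold a raw coordinate back into ``[0, grid_side)`` by wall reflection.

    Works for arbitrarily large overshoot (the triangle-wave map of period
    ``2 * (grid_side - 1)``); accepts scalars or integer arrays.
    """
    m = 2 * (grid_side - 1)
    z = np.mod(coord, m)
    out = np.where(z > grid_side - 1, m - z, z)
    if np.isscalar(coord):
        return int(out)
    return out.astype(np.int64)


def apply_move(position, step: int, direction: int, grid_side: int) -> tuple[int, int]:
    """Deterministic core of a move: position + step * direction, reflected."""
    vec = DIR_VECTORS[direction]
    nx = reflect_coordinate(int(position[0]) + step * int(vec[0]), grid_side)
    ny = reflect_coordinate(int(position[1]) + step * int(vec[1]), grid_side)
    return nx, ny


def move_all(positions: np.ndarray, config: SimConfig, rng: np.random.Generator):
    """One day of movement for every orangutan.

    Returns ``(new_positions, steps, directions)``; steps and directions are
    kept so day nests can later be placed along the day's path.
    """
    n = len(positions)
    g = config.grid_side
    steps = np.rint(
        rng.normal(config.move_mean_squares, config.move_spread_squares, size=n)
    ).astype(np.int64)
    np.maximum(steps, 0, out=steps)
    dirs = rng.integers(0, 8, size=n)
    x, y = positions[:, 0], positions[:, 1]
    on_edge = (x == 0) | (x == g - 1) | (y == 0) | (y == g - 1)
    for i in np.flatnonzero(on_edge):
        allowed = _allowed_directions(int(x[i]), int(y[i]), g)
        dirs[i] = allowed[rng.integers(len(allowed))]
    new = reflect_coordinate(positions + steps[:, None] * DIR_VECTORS[dirs], g)
    return new, steps, dirs


def daily_move(position, config: SimConfig, rng: np.random.Generator):
    """Move a single orangutan; returns its new ``(x, y)`` position."""
    pos = np.asarray(position, dtype=np.int64)[None, :]
    new, _, _ = move_all(pos, config, rng)
    return int(new[0, 0]), int(new[0, 1])


class NestArena:
    """Columnar store of every nest ever built in a run.

    Nests live in parallel numpy arrays (position, class, birth day, decay
    stage, per-stage durations, tagged and alive flags) plus a square ->
    arena-index occupancy map used to detect reuse-as-replacement. Ids are
    globally unique and never recycled; periodic compaction drops long-dead
    rows while preserving ids.
    """

    _CHUNK = 4096

    def __init__(self, grid_side: int):
        self.grid_side = grid_side
        self._cap = self._CHUNK
        self.n = 0
        self._next_id = 0
        self.id = np.zeros(self._cap, dtype=np.int64)
        self.x = np.zeros(self._cap, dtype=np.int32)
        self.y = np.zeros(self._cap, dtype=np.int32)
        self.klass = np.zeros(self._cap, dtype=np.int8)
        self.birth_day = np.zeros(self._cap, dtype=np.int32)
        self.stage = np.zeros(self._cap, dtype=np.int8)
        self.durations = np.zeros((self._cap, N_STAGES), dtype=np.float32)
        self.tagged = np.zeros(self._cap, dtype=bool)
        self.alive = np.zeros(self._cap, dtype=bool)
        self.occupancy: dict[int, int] = {}
        # running totals for diagnostics (reuse rate etc.)
        self.n_built = 0
        self.n_replaced = 0

    # -- storage management ----------------------------------------------
    def _grow(self, m: int) -> int:
        need = self.n + m
        if need > self._cap:
            new_cap = max(need, self._cap * 2)
            for name in ("id", "x", "y", "klass", "birth_day", "stage",
                         "tagged", "alive"):
                arr = getattr(self, name)
                grown = np.zeros(new_cap, dtype=arr.dtype)
                grown[: self.n] = arr[: self.n]
                setattr(self, name, grown)
            grown = np.zeros((new_cap, N_STAGES), dtype=np.float32)
            grown[: self.n] = self.durations[: self.n]
            self.durations = grown
            self._cap = new_cap
        start = self.n
        self.n += m
        return start

    def compact(self) -> None:
        """Drop dead rows (live nests keep their ids); rebuild occupancy."""
        keep = np.flatnonzero(self.alive[: self.n])
        for name in ("id", "x", "y", "klass", "birth_day", "stage",
                     "tagged", "alive"):
            arr = getattr(self, name)
            arr[: len(keep)] = arr[keep]
        self.durations[: len(keep)] = self.durations[keep]
        self.n = len(keep)
        self.occupancy = {
            int(self.x[i]) * self.grid_side + int(self.y[i]): i
            for i in range(self.n)
        }

    # -- queries -----------------------------------------------------------
    def live_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self.n])

    def n_live(self) -> int:
        return int(self.alive[: self.n].sum())

    def _key(self, x: int, y: int) -> int:
        return int(x) * self.grid_side + int(y)

    # -- mutation ----------------------------------------------------------
    def add(self, xs, ys, klass, day: int, durations) -> np.ndarray:
        """Insert nests; replaces any live nest already on the same square.

        Returns the arena indices of the inserted nests.
        """
        xs = np.atleast_1d(np.asarray(xs, dtype=np.int32))
        ys = np.atleast_1d(np.asarray(ys, dtype=np.int32))
        klass = np.broadcast_to(np.asarray(klass, dtype=np.int8), xs.shape)
        durations = np.atleast_2d(np.asarray(durations, dtype=np.float32))
        m = len(xs)
        start = self._grow(m)
        idx = np.arange(start, start + m)
        self.id[idx] = np.arange(self._next_id, self._next_id + m)
        self._next_id += m
        self.x[idx] = xs
        self.y[idx] = ys
        self.klass[idx] = klass
        self.birth_day[idx] = day
        self.stage[idx] = 0
        self.durations[idx] = durations
        self.tagged[idx] = False
        self.alive[idx] = True
        occ = self.occupancy
        for j in range(m):
            key = self._key(xs[j], ys[j])
            old = occ.get(key)
            if old is not None and self.alive[old]:
                self.alive[old] = False
                self.n_replaced += 1
            occ[key] = int(idx[j])
        self.n_built += m
        return idx

    def mark_dead(self, indices: np.ndarray) -> None:
        """Kill nests (decayed past stage E) and free their squares."""
        self.alive[indices] = False
        occ = self.occupancy
        for i in np.atleast_1d(indices):
            key = self._key(self.x[i], self.y[i])
            if occ.get(key) == int(i):
                del occ[key]


def draw_stage_durations(env: Environment, xs, ys, is_day, rng: np.random.Generator
                         ) -> np.ndarray:
    """Per-nest stage durations for nests built at squares ``(xs, ys)``.

    Each stage duration is drawn from Normal(type mean, type mean / 2) for
    the tree on the square, floored at ``MIN_DURATION_DAYS``, scaled by the
    altitudinal multiplier of the square's x coordinate, and divided by the
    day-nest factor for day nests.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=np.int64))
    ys = np.atleast_1d(np.asarray(ys, dtype=np.int64))
    is_day = np.broadcast_to(np.asarray(is_day, dtype=bool), xs.shape)
    means = env.stage_means_at(xs, ys)  # (m, 5)
    dur = rng.normal(means, means / 2.0)
    np.maximum(dur, MIN_DURATION_DAYS, out=dur)
    dur *= env.alt_by_x[xs][:, None]
    dur[is_day] /= env.config.day_nest_factor
    return dur


def build_nests(arena: NestArena, env: Environment, day: int,
                start_positions: np.ndarray, end_positions: np.ndarray,
                steps: np.ndarray, dirs: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Build the day's nests for every orangutan after its move.

    Every orangutan contributes one night nest at its end-of-day position;
    with probability ``day_nest_rate`` it also built one day nest at a
    uniformly random square along the day's straight-line path.
    Returns the arena indices of the new nests.
    """
    config = env.config
    n = len(end_positions)
    build_day = rng.random(n) < config.day_nest_rate
    day_idx = np.flatnonzero(build_day)
    # uniform position along the path: start + u * direction, u in [1, steps]
    day_xy = np.empty((len(day_idx), 2), dtype=np.int64)
    for j, i in enumerate(day_idx):
        k = int(steps[i])
        u = int(rng.integers(1, k + 1)) if k > 0 else 0
        day_xy[j] = apply_move(start_positions[i], u, int(dirs[i]),
                               config.grid_side)
    xs = np.concatenate([end_positions[:, 0], day_xy[:, 0]])
    ys = np.concatenate([end_positions[:, 1], day_xy[:, 1]])
    klass = np.concatenate([np.full(n, NIGHT, dtype=np.int8),
                            np.full(len(day_idx), DAY, dtype=np.int8)])
    dur = draw_stage_durations(env, xs, ys, klass == DAY, rng)
    return arena.add(xs, ys, klass, day, dur)


def build_nests_for_day(arena: NestArena, env: Environment, day: int,
                        start_position, end_position, step: int, direction: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Single-orangutan convenience wrapper around :func:`build_nests`."""
    return build_nests(
        arena, env, day,
        np.asarray(start_position, dtype=np.int64)[None, :],
        np.asarray(end_position, dtype=np.int64)[None, :],
        np.asarray([step]), np.asarray([direction]), rng,
    )


def remove_fraction(positions: np.ndarray, fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Remove ``round(fraction * n)`` individuals uniformly at random.

    Rounding is half-up so the removal count is deterministic. Removed
    individuals build no further nests; their existing nests are unaffected.
    """
    if not (0.0 <= fraction < 1.0):
        raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
    n = len(positions)
    k = int(np.floor(fraction * n + 0.5))
    if k == 0:
        return positions
    drop = rng.choice(n, size=k, replace=False)
    keep = np.setdiff1d(np.arange(n), drop, assume_unique=True)
    return positions[keep]
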
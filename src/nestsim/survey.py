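"""Strip-transect placement and repeated nest surveys.

Transects are axis-aligned rectangles of whole squares, ten squares
(20 m) wide, placed uniformly at random with the constraint that each
rectangle lies entirely inside the grid and transects do not overlap.
Surveys revisit the same transects every 30 days. Under *incomplete
visibility* an untagged nest inside a transect is detected with a
stage-dependent probability (defaults 0.90/0.95/0.95/0.85/0.80 for
stages A-E); under *complete visibility* with probability 0.99. A detected
nest is tagged and is then recorded on every later survey for as long as
it exists, emulating physical nest tags.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agents import KLASS_NAMES, NestArena
from .config import STAGES, SimConfig
from .errors import PlacementError

INCOMPLETE = "incomplete"
COMPLETE = "complete"

#: schema of the observation table; the estimators' sole input
OBS_COLUMNS = ("survey_index", "day", "transect_id", "nest_id", "stage",
               "first_detection", "klass")


@dataclasses.dataclass(frozen=True)
class Transect:
    """An axis-aligned survey strip.

    ``origin`` is the minimum-coordinate corner; a horizontal transect
    extends ``length`` squares along x and ``width`` along y, a vertical
    one the other way round.
    """

    id: int
    origin: tuple[int, int]
    orientation: str  # "horizontal" | "vertical"
    length: int
    width: int

    @property
    def rect(self) -> tuple[int, int, int, int]:
        """(x0, x1, y0, y1) half-open square ranges."""
        x0, y0 = self.origin
        if self.orientation == "horizontal":
            return x0, x0 + self.length, y0, y0 + self.width
        return x0, x0 + self.width, y0, y0 + self.length

    def contains(self, x, y):
        x0, x1, y0, y1 = self.rect
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    def area_squares(self) -> int:
        return self.length * self.width


def _overlaps(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


def place_transects(n: int, length: int, config: SimConfig,
                    rng: np.random.Generator, width: int | None = None,
                    max_tries: int = 1000) -> list[Transect]:
    """Place ``n`` non-overlapping transects of ``length`` squares.

    Positions are drawn uniformly among placements that keep the whole
    rectangle inside the grid; orientation is horizontal or vertical with
    equal probability. Placement is fixed for the rest of the run.

    Raises
    ------
    PlacementError
        If a non-overlapping placement cannot be found in ``max_tries``
        attempts per transect (e.g. the transects do not fit).
    """
    width = config.strip_width_squares if width is None else width
    g = config.grid_side
    if length > g or width > g:
        raise PlacementError(f"transect {length}x{width} does not fit in grid {g}")
    placed: list[Transect] = []
    rects: list[tuple[int, int, int, int]] = []
    for tid in range(n):
        for _ in range(max_tries):
            horizontal = bool(rng.integers(2))
            lx, ly = (length, width) if horizontal else (width, length)
            ox = int(rng.integers(0, g - lx + 1))
            oy = int(rng.integers(0, g - ly + 1))
            tr = Transect(id=tid, origin=(ox, oy),
                          orientation="horizontal" if horizontal else "vertical",
                          length=length, width=width)
            if not any(_overlaps(tr.rect, r) for r in rects):
                placed.append(tr)
                rects.append(tr.rect)
                break
        else:
            raise PlacementError(
                f"could not place transect {tid} without overlap after "
                f"{max_tries} tries")
    return placed


def total_transect_length_m(transects: Sequence[Transect], config: SimConfig) -> float:
    """Total transect length L in metres (the denominator of nest density)."""
    return sum(t.length for t in transects) * config.square_size


def sampled_fraction(transects: Sequence[Transect], config: SimConfig) -> float:
    """Fraction of the study area covered by the transect strips."""
    return sum(t.area_squares() for t in transects) / config.grid_side ** 2


def run_survey(arena: NestArena, transects: Sequence[Transect], visibility: str,
               config: SimConfig, rng: np.random.Generator,
               survey_index: int, day: int) -> list[tuple]:
    """Survey every transect once; returns observation rows and tags nests.

    A live nest inside a transect is always recorded if it was detected on
    any earlier survey (it carries a tag); otherwise it is detected with
    the stage detection probability (incomplete visibility) or with the
    complete-visibility probability (0.99). Newly detected nests get
    ``first_detection = 1`` and become tagged.
    """
    if visibility not in (INCOMPLETE, COMPLETE):
        raise ValueError(f"visibility must be '{INCOMPLETE}' or '{COMPLETE}'")
    detect = np.asarray(config.detect_prob_by_stage, dtype=float)
    live = arena.live_indices()
    xs = arena.x[live]
    ys = arena.y[live]
    rows: list[tuple] = []
    for tr in transects:
        inside = live[tr.contains(xs, ys)]
        if inside.size == 0:
            continue
        tagged = arena.tagged[inside]
        stages = arena.stage[inside]
        if visibility == COMPLETE:
            p = np.full(inside.size, config.complete_visibility_prob)
        else:
            p = detect[stages]
        seen = tagged | (rng.random(inside.size) < p)
        hit = inside[seen]
        first = ~arena.tagged[hit]
        arena.tagged[hit] = True
        for i, f in zip(hit, first):
            rows.append((survey_index, day, tr.id, int(arena.id[i]),
                         STAGES[arena.stage[i]], int(f),
                         KLASS_NAMES[arena.klass[i]]))
    return rows


def observations_to_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build an observation table DataFrame from survey rows."""
    df = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    return df.astype({
        "survey_index": np.int64, "day": np.int64, "transect_id": np.int64,
        "nest_id": np.int64, "stage": str, "first_detection": np.int64,
        "klass": str,
    })


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return observations_to_frame([tuple(r) for r in df[list(OBS_COLUMNS)].itertuples(index=False)])
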
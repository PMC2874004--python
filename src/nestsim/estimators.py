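"""Population-size estimators operating on observation tables.

Both estimators convert an observed nest count N into a nest density

    d_nest = N / (L * w)

with L the total transect length and w the strip width (metres), and then
into an orangutan density

    d_orang = d_nest / (p * r * t * o)

where p is the proportion of individuals that build nests, r the nest
construction rate (nests per individual per day), t a time span in days
and o the proportion of nests seen. The two methods differ in what N, t
and o mean:

* **marked recount** -- N counts only nests *first* detected on the second
  or later survey, t is the span between the first and last survey, and o
  averages the detection probabilities of fresh stages A and B. No decay
  time is needed.
* **matrix method** -- N is the mean standing count per survey (all
  recorded nests), o averages the detection probabilities of all five
  stages, and t is the expected nest visibility time obtained from an
  absorbing Markov chain fitted to the observed stage transitions: with Q
  the transient block of the transition matrix, the fundamental matrix
  N_f = (I - Q)^-1 row-summed from the fresh state gives the expected
  number of inter-survey intervals before disappearance, which is scaled
  by the survey interval and a correction factor (0.89) compensating the
  under-sampling of short-lived nests.

A published mean decay time from another site can be substituted for the
fitted one to gauge the cost of borrowing decay rates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .config import N_STAGES, STAGES, SimConfig
from .errors import (InsufficientDataError, ParameterError, UndefinedDecayError)
from .survey import COMPLETE, INCOMPLETE, Transect, total_transect_length_m

DISAPPEARED = N_STAGES  # column index of the absorbing state in the count matrix


@dataclasses.dataclass
class EstimatorParams:
    """Shared conversion parameters for both estimators.

    ``o`` and (for the matrix method) ``t`` are supplied by the caller:
    following the design of the study the true model detection
    probabilities are handed to the estimators so the conversion itself
    introduces no bias.
    """

    L: float                 # total transect length, metres
    w: float                 # strip width, metres
    area: float              # study area, m^2
    p: float = 1.0           # proportion of nest builders
    r: float = 1.2           # nests built per orangutan per day
    o: float = 1.0           # proportion of nests seen
    t: float | None = None   # days (method-specific; set by the estimator)

    def validate(self) -> "EstimatorParams":
        if not (0.0 < self.p <= 1.0):
            raise ParameterError(f"p must be in (0, 1], got {self.p}")
        if not (0.0 < self.o <= 1.0):
            raise ParameterError(f"o must be in (0, 1], got {self.o}")
        for name in ("r", "L", "w", "area"):
            v = getattr(self, name)
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        if self.t is not None and self.t <= 0:
            raise ParameterError(f"t must be > 0, got {self.t}")
        return self

    @classmethod
    def for_survey(cls, config: SimConfig, transects: Sequence[Transect],
                   method: str, visibility: str, **overrides) -> "EstimatorParams":
        """Build params for a survey design, filling in the o convention.

        ``o`` is the stage-A/B mean detection probability for the marked
        recount method and the all-stage mean for the matrix method; under
        complete visibility both equal the complete-visibility probability.
        """
        detect = np.asarray(config.detect_prob_by_stage, dtype=float)
        if visibility == COMPLETE:
            o = config.complete_visibility_prob
        elif visibility == INCOMPLETE:
            o = float(detect[:2].mean()) if method == "marked" else float(detect.mean())
        else:
            raise ParameterError(f"unknown visibility mode '{visibility}'")
        kwargs = dict(
            L=total_transect_length_m(transects, config),
            w=config.strip_width_m,
            area=config.area_m2,
            r=config.nest_build_rate_r,
            o=o,
        )
        kwargs.update(overrides)
        return cls(**kwargs).validate()


@dataclasses.dataclass
class TransitionModel:
    """Stage-transition counts and the derived absorbing chain.

    ``counts`` is 5x6 (rows: source stages A-E; columns: destination
    stages A-E plus disappearance). ``states`` lists the stage indices
    retained in the transient block (stages never observed as a source
    are dropped), and ``Q`` is the row-normalized transient block over
    those states.
    """

    counts: np.ndarray
    states: list[int]
    Q: np.ndarray

    @property
    def n_disappearances(self) -> int:
        return int(self.counts[:, DISAPPEARED].sum())

    def fundamental(self) -> np.ndarray:
        """(I - Q)^-1; raises :class:`UndefinedDecayError` if singular."""
        eye = np.eye(len(self.states))
        try:
            fund = np.linalg.inv(eye - self.Q)
        except np.linalg.LinAlgError:
            raise UndefinedDecayError("no-complete-decay") from None
        if not np.all(np.isfinite(fund)) or np.any(fund < -1e-9):
            raise UndefinedDecayError("no-complete-decay")
        return fund


@dataclasses.dataclass
class EstimateRecord:
    """One population estimate (or a recorded failure to produce one)."""

    method: str
    replicate: int = 0
    window: tuple[int, int] | None = None
    n_obs: float = 0.0
    estimate: float | None = None
    status: str = "ok"
    reason: str | None = None
    t_days: float | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = None if self.window is None else f"{self.window[0]}-{self.window[1]}"
        return d


# ---------------------------------------------------------------------------
# density arithmetic
# ---------------------------------------------------------------------------

def nest_density(N: float, L: float, w: float) -> float:
    """Nests per square metre: N / (L * w)."""
    if N < 0:
        raise ParameterError(f"nest count must be >= 0, got {N}")
    if L <= 0 or w <= 0:
        raise ParameterError("L and w must be > 0")
    return N / (L * w)


def orangutan_density(d_nest: float, params: EstimatorParams) -> float:
    """Orangutans per square metre: d_nest / (p * r * t * o)."""
    params.validate()
    if params.t is None or params.t <= 0:
        raise ParameterError("params.t must be set and > 0")
    denom = params.p * params.r * params.t * params.o
    if denom == 0:
        raise ParameterError("p * r * t * o must be nonzero")
    return d_nest / denom


def _population(N: float, params: EstimatorParams) -> float:
    return orangutan_density(nest_density(N, params.L, params.w), params) * params.area


# ---------------------------------------------------------------------------
# marked recount
# ---------------------------------------------------------------------------

def _survey_days(obs: pd.DataFrame) -> pd.Series:
    days = obs.groupby("survey_index")["day"].first().sort_index()
    if len(days) < 2:
        raise InsufficientDataError(
            f"need >= 2 surveys, observation table has {len(days)}")
    return days


def marked_recount_estimate(obs: pd.DataFrame, params: EstimatorParams,
                            replicate: int = 0) -> EstimateRecord:
    """Population estimate from nests newly discovered after the first survey.

    N is the number of first detections on the second and later surveys of
    the window and t the number of days between the first and last survey.
    """
    days = _survey_days(obs)
    first, last = days.index.min(), days.index.max()
    t = float(days.loc[last] - days.loc[first])
    new = obs[(obs["survey_index"] > first) & (obs["first_detection"] == 1)]
    N = float(len(new))
    p = dataclasses.replace(params, t=t)
    return EstimateRecord(method="marked", replicate=replicate,
                          window=(int(first), int(last)), n_obs=N,
                          estimate=_population(N, p), t_days=t)


# ---------------------------------------------------------------------------
# matrix method
# ---------------------------------------------------------------------------

def fit_transition_matrix(obs: pd.DataFrame,
                          survey_indices: Sequence[int] | None = None
                          ) -> TransitionModel:
    """Pool stage transitions over all consecutive survey pairs.

    For each nest recorded at surveys k and k+1 a count is added from its
    stage at k to its stage at k+1 (stages may be skipped over a 30-day
    interval). A nest recorded at k but absent at k+1 must have
    disappeared -- recorded nests are tagged and tagged nests are always
    recorded while they exist -- and contributes to the absorbing column.

    ``survey_indices`` is the full survey schedule; supply it when a survey
    may have recorded nothing at all (such a survey is absent from the
    table, yet the disappearances it witnessed are real data). By default
    only the surveys present in the table are used.
    """
    if survey_indices is None:
        surveys = list(_survey_days(obs).index)
    else:
        surveys = sorted(survey_indices)
        if len(surveys) < 2:
            raise InsufficientDataError("need >= 2 surveys in the schedule")
    stage_idx = obs["stage"].map({s: i for i, s in enumerate(STAGES)})
    if stage_idx.isna().any():
        bad = obs.loc[stage_idx.isna(), "stage"].iloc[0]
        raise ParameterError(f"unknown decay stage {bad!r} in observation table")
    by_survey = {
        k: dict(zip(obs.loc[sel, "nest_id"], stage_idx[sel]))
        for k, sel in obs.groupby("survey_index").groups.items()
    }
    counts = np.zeros((N_STAGES, N_STAGES + 1), dtype=np.int64)
    for k, k_next in zip(surveys[:-1], surveys[1:]):
        now = by_survey.get(k, {})
        nxt = by_survey.get(k_next, {})
        for nest, s in now.items():
            s2 = nxt.get(nest, DISAPPEARED)
            counts[s, s2] += 1
    if counts.sum() == 0:
        raise InsufficientDataError("no stage transitions observed")
    # stages never observed as a source carry no sojourn information and are
    # deleted from the transient set; deletion is iterated because a row whose
    # only observed exits lead to deleted states becomes empty itself
    kept = {s for s in range(N_STAGES) if counts[s].sum() > 0}
    while True:
        dead = {s for s in kept
                if counts[s, DISAPPEARED] + sum(counts[s, t] for t in kept) == 0}
        if not dead:
            break
        kept -= dead
    if not kept:
        raise InsufficientDataError("no usable stage transitions")
    states = sorted(kept)
    sub = counts[np.ix_(states, states)].astype(float)
    absorbed = counts[states, DISAPPEARED].astype(float)
    row_tot = sub.sum(axis=1) + absorbed
    Q = sub / row_tot[:, None]
    return TransitionModel(counts=counts, states=states, Q=Q)


def expected_decay_time(model: TransitionModel, interval_days: float = 30.0,
                        correction: float = 0.89) -> float:
    """Expected nest visibility time in days from the fitted chain.

    Sums the fundamental-matrix row of the fresh state (stage A, or the
    earliest retained stage if A carried no usable transitions), scales
    by the survey interval and applies the short-lived-nest correction
    factor.
    """
    if model.n_disappearances == 0:
        raise UndefinedDecayError("no-complete-decay")
    fund = model.fundamental()
    sojourn_intervals = float(fund[0].sum())
    if not np.isfinite(sojourn_intervals) or sojourn_intervals <= 0:
        raise UndefinedDecayError("no-complete-decay")
    return sojourn_intervals * interval_days * correction


def _schedule(obs: pd.DataFrame, survey_indices: Sequence[int] | None
              ) -> list[int]:
    if survey_indices is None:
        return [int(k) for k in _survey_days(obs).index]
    surveys = sorted(int(k) for k in survey_indices)
    if len(surveys) < 2:
        raise InsufficientDataError("need >= 2 surveys in the schedule")
    return surveys


def matrix_estimate(obs: pd.DataFrame, params: EstimatorParams,
                    replicate: int = 0, interval_days: float = 30.0,
                    correction: float = 0.89,
                    survey_indices: Sequence[int] | None = None
                    ) -> EstimateRecord:
    """Population estimate from the standing crop and the fitted decay time.

    N is the mean number of recorded nests per survey. An unestimable
    decay time (no nest observed to disappear) yields a record with
    status ``undefined`` rather than an exception, so experiment summaries
    can report how often the method fails.
    """
    surveys = _schedule(obs, survey_indices)
    first, last = surveys[0], surveys[-1]
    per_survey = obs.groupby("survey_index").size().reindex(surveys, fill_value=0)
    N = float(per_survey.mean())
    if N == 0:
        return EstimateRecord(method="matrix", replicate=replicate,
                              window=(first, last), n_obs=0.0, estimate=0.0)
    try:
        model = fit_transition_matrix(obs, survey_indices=surveys)
        t = expected_decay_time(model, interval_days=interval_days,
                                correction=correction)
    except (UndefinedDecayError, InsufficientDataError) as err:
        reason = getattr(err, "reason", "insufficient-data")
        return EstimateRecord(method="matrix", replicate=replicate,
                              window=(first, last), n_obs=N, estimate=None,
                              status="undefined", reason=reason)
    p = dataclasses.replace(params, t=t)
    return EstimateRecord(method="matrix", replicate=replicate,
                          window=(first, last), n_obs=N,
                          estimate=_population(N, p), t_days=t)


def estimate_with_published_decay(obs: pd.DataFrame, assumed_decay_days: float,
                                  params: EstimatorParams, replicate: int = 0,
                                  apply_correction: bool = False,
                                  correction: float = 0.89,
                                  survey_indices: Sequence[int] | None = None
                                  ) -> EstimateRecord:
    """Matrix-method estimate with a borrowed mean decay time.

    Identical to :func:`matrix_estimate` except that ``t`` is the supplied
    published decay time instead of the fitted one. Published values are
    end-to-end mean visibility times, so the short-lived-nest correction is
    skipped by default (set ``apply_correction=True`` to apply it anyway).
    """
    if assumed_decay_days <= 0:
        raise ParameterError(
            f"assumed_decay_days must be > 0, got {assumed_decay_days}")
    surveys = _schedule(obs, survey_indices)
    first, last = surveys[0], surveys[-1]
    per_survey = obs.groupby("survey_index").size().reindex(surveys, fill_value=0)
    N = float(per_survey.mean())
    t = assumed_decay_days * (correction if apply_correction else 1.0)
    p = dataclasses.replace(params, t=t)
    return EstimateRecord(method="published", replicate=replicate,
                          window=(first, last), n_obs=N,
                          estimate=_population(N, p), t_days=t)
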
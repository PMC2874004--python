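"""Replicated experiment harnesses and their summaries.

Four experiment families are provided, mirroring the questions a survey
planner would ask of the simulator:

* ``visibility_bias`` -- how many surveys are needed before the marked
  recount method recovers from nests missed on the first pass, under
  stage-dependent (incomplete) visibility;
* ``effort_sweep`` -- accuracy and precision of both estimators as the
  number of transects grows, under near-perfect (complete) visibility;
* ``published_decay`` -- the error introduced by borrowing a mean nest
  decay time from another site instead of fitting it on-site;
* ``decline`` -- the probability that rolling four-survey estimates flag
  a 5%-per-year population decline relative to a baseline estimate.

Every replicate runs a fresh environment and population from its own
deterministically spawned seed, burns in to the first survey day, and
surveys one fixed set of transects at 30-day intervals.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .errors import ParameterError, SummaryError
from .estimators import (EstimateRecord, EstimatorParams, _population,
                         marked_recount_estimate, matrix_estimate,
                         estimate_with_published_decay)
from .simulation import run_survey_series
from .survey import COMPLETE

EXPERIMENTS = ("visibility_bias", "effort_sweep", "published_decay", "decline")

#: four consecutive monthly surveys form one estimation block ("period")
BLOCK = 4
#: three four-month periods make up one year of monitoring
PERIODS_PER_YEAR = 3
DAYS_PER_YEAR = 365


@dataclasses.dataclass
class ExperimentSpec:
    """Design of a replicated experiment."""

    experiment: str = "effort_sweep"
    n_replicates: int = 100
    n_surveys: int = 6
    n_transects: int = 13
    transect_length_squares: int = 500
    visibility: str = COMPLETE
    decline_rate: float = 0.05
    duration_years: int = 7
    assumed_decay_days: tuple[float, ...] = (72.0, 424.0)
    seed: int = 0

    def validate(self) -> "ExperimentSpec":
        if self.experiment not in EXPERIMENTS:
            raise ParameterError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.n_surveys < 2:
            raise ParameterError("n_surveys must be >= 2")
        if self.n_transects < 1 or self.transect_length_squares < 1:
            raise ParameterError("transect design must be positive")
        if not (0.0 <= self.decline_rate < 1.0):
            raise ParameterError("decline_rate must be in [0, 1)")
        if self.duration_years < 1:
            raise ParameterError("duration_years must be >= 1")
        return self


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _records_frame(records: Sequence[EstimateRecord], **extra) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in records])
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# constant-population replicates
# ---------------------------------------------------------------------------

def run_replicates(spec: ExperimentSpec, config: SimConfig | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one survey condition ``n_replicates`` times with both estimators.

    Returns ``(records, summary)``: one estimate row per replicate and
    method (undefined matrix estimates are recorded, not dropped), plus
    the per-method summary against the true population size. When the
    spec's experiment is ``published_decay``, borrowed-decay estimates
    for each assumed decay time are included as additional methods.
    """
    spec.validate()
    config = (config or SimConfig()).validate()
    records: list[EstimateRecord] = []
    for rep, rng in enumerate(_replicate_rngs(spec.seed, spec.n_replicates)):
        obs, transects, _ = run_survey_series(
            config, spec.n_transects, spec.transect_length_squares,
            spec.n_surveys, spec.visibility, rng=rng)
        marked_params = EstimatorParams.for_survey(config, transects, "marked",
                                                   spec.visibility)
        matrix_params = EstimatorParams.for_survey(config, transects, "matrix",
                                                   spec.visibility)
        schedule = list(range(1, spec.n_surveys + 1))
        records.append(marked_recount_estimate(obs, marked_params, replicate=rep))
        records.append(matrix_estimate(
            obs, matrix_params, replicate=rep,
            interval_days=config.survey_interval_days,
            correction=config.correction_factor, survey_indices=schedule))
        if spec.experiment == "published_decay":
            for assumed in spec.assumed_decay_days:
                rec = estimate_with_published_decay(obs, assumed, matrix_params,
                                                    replicate=rep,
                                                    survey_indices=schedule)
                rec.method = f"published_{assumed:g}d"
                records.append(rec)
    df = _records_frame(records, visibility=spec.visibility,
                        n_transects=spec.n_transects,
                        n_surveys=spec.n_surveys)
    return df, summarize(df, truth=config.n_orangutans)


def summarize(records: pd.DataFrame, truth: float) -> pd.DataFrame:
    """Per-method summary: median, IQR, share within +/-33% of the truth.

    Undefined estimates are excluded from the quantiles but their count
    and fraction are reported alongside.
    """
    if len(records) == 0 or (records["status"] == "ok").sum() == 0:
        raise SummaryError("no defined estimates to summarize")
    rows = []
    for method, grp in records.groupby("method", sort=False):
        ok = grp[grp["status"] == "ok"]["estimate"].astype(float)
        n_undef = int((grp["status"] != "ok").sum())
        if len(ok) == 0:
            rows.append(dict(method=method, n=0, median=np.nan, q25=np.nan,
                             q75=np.nan, iqr=np.nan, prop_within_33pct=np.nan,
                             n_undefined=n_undef, frac_undefined=1.0))
            continue
        q25, med, q75 = ok.quantile([0.25, 0.5, 0.75])
        within = ((ok >= 0.67 * truth) & (ok <= 1.33 * truth)).mean()
        rows.append(dict(method=method, n=len(ok), median=med, q25=q25, q75=q75,
                         iqr=q75 - q25, prop_within_33pct=float(within),
                         n_undefined=n_undef,
                         frac_undefined=n_undef / len(grp)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decline detection
# ---------------------------------------------------------------------------

def _removal_schedule(rate: float, last_day: int) -> dict[int, float]:
    """5%-per-year style removals on day 1 of each 365-day calendar year."""
    if rate <= 0:
        return {}
    return {k * DAYS_PER_YEAR + 1: rate
            for k in range(last_day // DAYS_PER_YEAR + 1)}


def _block_surveys(n_blocks: int) -> list[list[int]]:
    """1-based survey indices of the baseline block and each later block."""
    return [list(range(1 + b * BLOCK, 1 + (b + 1) * BLOCK))
            for b in range(n_blocks)]


def _marked_block_estimate(obs: pd.DataFrame, block: list[int],
                           params: EstimatorParams, interval: float) -> float:
    """Marked recount within one four-survey block.

    Under continuous monthly surveying every nest present at the block's
    first survey is (almost surely) already tagged, so first detections at
    the block's later surveys count nests built during the block; t is the
    block's 90-day span.
    """
    sel = obs["survey_index"].isin(block[1:]) & (obs["first_detection"] == 1)
    N = float(sel.sum())
    t = interval * (len(block) - 1)
    return _population(N, dataclasses.replace(params, t=t))


def _matrix_block_estimate(obs: pd.DataFrame, block: list[int],
                           params: EstimatorParams, interval: float,
                           correction: float) -> EstimateRecord:
    sub = obs[obs["survey_index"].isin(block)]
    return matrix_estimate(sub, params, interval_days=interval,
                           correction=correction, survey_indices=block)


def decline_experiment(spec: ExperimentSpec, config: SimConfig | None = None,
                       ) -> dict[str, pd.DataFrame]:
    """Monitor a declining population and score decline detections.

    Each replicate removes ``decline_rate`` of the remaining population on
    day 1 of every 365-day year and surveys monthly from the first survey
    day, for ``4 + 12 * duration_years`` surveys: a four-survey baseline
    block followed by three four-survey periods per monitored year. Every
    period's estimate is coded 1 if strictly below the baseline estimate.

    Returns ``periods`` (per method and period: detection proportion over
    replicates with a defined baseline and period estimate), ``years``
    (each year averages its three periods, with an exact two-tailed
    binomial p-value against chance 0.5 on the pooled detections) and
    ``failures`` (replicates whose matrix baseline was undefined because
    no nest completely decayed -- these are excluded from the matrix
    summaries, with the count reported, not silently dropped).
    """
    spec.validate()
    config = (config or SimConfig()).validate()
    n_surveys = BLOCK * (1 + PERIODS_PER_YEAR * spec.duration_years)
    interval = config.survey_interval_days
    last_day = config.first_survey_day + (n_surveys - 1) * interval
    removals = _removal_schedule(spec.decline_rate, last_day)
    blocks = _block_surveys(1 + PERIODS_PER_YEAR * spec.duration_years)
    n_periods = len(blocks) - 1

    detect = {m: np.full((spec.n_replicates, n_periods), np.nan)
              for m in ("marked", "matrix")}
    matrix_baseline_failures = 0
    for rep, rng in enumerate(_replicate_rngs(spec.seed, spec.n_replicates)):
        obs, transects, _ = run_survey_series(
            config, spec.n_transects, spec.transect_length_squares,
            n_surveys, spec.visibility, rng=rng, removal_days=removals)
        mk = EstimatorParams.for_survey(config, transects, "marked",
                                        spec.visibility)
        mx = EstimatorParams.for_survey(config, transects, "matrix",
                                        spec.visibility)
        base_marked = _marked_block_estimate(obs, blocks[0], mk, interval)
        base_matrix = _matrix_block_estimate(obs, blocks[0], mx, interval,
                                             config.correction_factor)
        if base_matrix.status != "ok":
            matrix_baseline_failures += 1
        for j, block in enumerate(blocks[1:]):
            est = _marked_block_estimate(obs, block, mk, interval)
            detect["marked"][rep, j] = float(est < base_marked)
            if base_matrix.status == "ok":
                rec = _matrix_block_estimate(obs, block, mx, interval,
                                             config.correction_factor)
                if rec.status == "ok":
                    detect["matrix"][rep, j] = float(rec.estimate
                                                     < base_matrix.estimate)

    period_rows, year_rows = [], []
    for method, mat in detect.items():
        for j in range(n_periods):
            col = mat[:, j]
            defined = ~np.isnan(col)
            n_def = int(defined.sum())
            k = int(np.nansum(col))
            period_rows.append(dict(
                method=method, period=j + 1, year=1 + j // PERIODS_PER_YEAR,
                n_detect=k, n_defined=n_def,
                proportion=k / n_def if n_def else np.nan))
        for year in range(1, spec.duration_years + 1):
            cols = mat[:, (year - 1) * PERIODS_PER_YEAR: year * PERIODS_PER_YEAR]
            k, n_def = int(np.nansum(cols)), int((~np.isnan(cols)).sum())
            year_rows.append(dict(
                method=method, year=year, n_detect=k, n_defined=n_def,
                proportion=k / n_def if n_def else np.nan,
                p_value=binomial_two_tailed(k, n_def) if n_def else np.nan))
    failures = pd.DataFrame([dict(method="matrix",
                                  n_baseline_undefined=matrix_baseline_failures,
                                  n_replicates=spec.n_replicates)])
    return {"periods": pd.DataFrame(period_rows),
            "years": pd.DataFrame(year_rows),
            "failures": failures}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial test computed from the binomial pmf.

    The p-value sums the probabilities of every outcome whose probability
    under ``Binomial(n, p0)`` does not exceed that of the observed ``k``.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ParameterError("k and n must be integers")
    if n < 0 or not (0 <= k <= n):
        raise ParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ParameterError(f"p0 must be in [0, 1], got {p0}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    p_obs = pmf[k]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def run_experiment(spec: ExperimentSpec, config: SimConfig | None = None,
                   ) -> dict[str, pd.DataFrame]:
    """Run the experiment family named by ``spec.experiment``.

    ``visibility_bias`` sweeps the number of surveys (2..10, incomplete
    visibility); ``effort_sweep`` sweeps the number of transects (1..10);
    the other families run a single condition.
    """
    spec.validate()
    config = (config or SimConfig()).validate()
    if spec.experiment == "decline":
        return decline_experiment(spec, config)
    if spec.experiment == "published_decay":
        records, summary = run_replicates(spec, config)
        return {"estimates": records, "summary": summary}

    if spec.experiment == "visibility_bias":
        grid = [dataclasses.replace(spec, n_surveys=k, visibility="incomplete")
                for k in (2, 4, 6, 8, 10)]
        label = "n_surveys"
    else:  # effort_sweep
        grid = [dataclasses.replace(spec, n_transects=k) for k in
                range(1, spec.n_transects + 1)]
        label = "n_transects"
    all_records, all_summaries = [], []
    for sub in grid:
        records, summary = run_replicates(sub, config)
        summary[label] = getattr(sub, label)
        all_records.append(records)
        all_summaries.append(summary)
    return {"estimates": pd.concat(all_records, ignore_index=True),
            "summary": pd.concat(all_summaries, ignore_index=True)}
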
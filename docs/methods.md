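# Methods

## The simulated world

The environment is a square grid of `grid_side × grid_side` squares
(default 5000, each 2 m × 2 m, i.e. 100 km²). At initialization every
square receives one tree whose type is drawn equiprobably from
`n_tree_types` (4) types; trees are immutable for the run and spatially
uncorrelated (real forests are patchier — see *Limitations*).

Nest decay is stage-structured: every nest passes A → B → C → D → E →
gone. The mean sojourn time of stage *s* for tree type *k* is drawn once
per run from Normal(`stage_mean_days[s]`, `stage_spread_days[s]`) —
defaults 5, 20, 40, 80, 120 days with spreads equal to half the means —
so the stage structure differs between runs the way decay regimes differ
between field sites. Each individual nest then draws its own stage
durations from Normal(type mean, type mean / 2). All normal draws are
floored at 0.5 day so daily hazards stay finite. An altitudinal gradient
multiplies a nest's durations by

    m(x) = 1 + β (x − x_mid) / x_mid ,

linear and increasing along the x axis with m(x_mid) = 1. β defaults
to 0.3 (multiplier range 0.7–1.3, matching the intended ~370 m elevation
span) and is a first-class config field because the original gradient's
exact slope is not recoverable; the gradient is symmetric, so it adds
variance but leaves the area-mean decay time unchanged.

## Orangutans and nest construction

`n_orangutans` (200; 2 / km²) adults move once per day: a step count
~Normal(350, 100) squares (700 ± 200 m), rounded and floored at 0, in one
of eight compass directions drawn uniformly. Distance is counted in
squares, so diagonal moves cover the same number of squares as cardinal
ones. The boundary is reflecting twice over: at an edge square the
direction set is restricted to directions pointing inward, and any
overshoot is folded back off the wall (triangle-wave reflection).
Reflection rather than end-point clamping matters: clamping parks agents
on the one-dimensional boundary rows, which concentrates nests there and
inflates the nest-replacement rate several-fold.

After moving, the orangutan builds one night nest at its end position;
with probability `day_nest_rate` (0.2) it also built one day nest at a
uniformly random square along the day's straight-line path (a single
Bernoulli per day reproduces the 0.2/day expectation without
sub-stepping). Day nests are identical except all stage durations are
divided by `day_nest_factor` (1.667). Total construction rate is
r = 1.2 nests/individual/day. A nest built on a square holding a live
nest *replaces* it: the old nest dies, the new one starts fresh and
untagged. At equilibrium this affects ~0.3–0.5 % of new nests (the field
guidance is "about 1 %"; reuse in this model arises only from chance
revisits of a 2 m square, with no behavioural preference for old sites).

Population decline experiments remove round(fraction × remaining)
individuals (round-half-up, for determinism) uniformly at random on day 1
of each 365-day year; their existing nests decay normally.

## Nest decay dynamics

One seasonal factor is shared by the whole grid per day. It starts at
1.0 and performs a Gaussian random walk (daily increment Normal(0, 0.05))
hard-clamped to [0.625, 1.6] — so realized daily hazards vary by up to
2.56× over time, with lag-1 autocorrelation > 0.9. A nest in stage *s*
advances each day with probability clamp(factor / duration_s, 0, 1), a
geometric sojourn with mean equal to the duration at factor 1. With all
multipliers at 1 the expected lifetime is the sum of the stage means,
265 days.

Two consequences of these choices are worth stating because they shape
the standing crop. The bounds (0.625, 1.6) are symmetric on a log scale
but not arithmetically, so the walk's long-run mean sits near 1.1 and
nests decay slightly faster than the nominal 265 days on average; and day
nests (1/6 of construction) live 1.667× shorter. The equilibrium
standing crop therefore corresponds to an effective visibility near 230
days rather than 265 — the model's own behaviour, visible in the matrix
method's fitted decay times.

## Surveys

Transects are axis-aligned rectangles, `strip_width_squares` (10 squares
= 20 m) wide, placed uniformly at random, wholly in-grid and
non-overlapping (so no nest can be double-counted), fixed for the run.
Surveys start on `first_survey_day` (1000) and repeat every 30 days. A
live nest inside a transect is recorded: always, if tagged (detected on
any earlier survey); otherwise with the stage-specific detection
probability (0.90/0.95/0.95/0.85/0.80 for A–E) under *incomplete*
visibility, or 0.99 under *complete* visibility. Detection trials are
independent across surveys, and a previously missed nest is re-tried at
its *current* (older) stage. A replaced nest inherits nothing from its
predecessor — the old id disappears, the new id is untagged.

The observation table (one row per nest per survey: survey_index, day,
transect_id, nest_id, stage, first_detection, klass) is the estimators'
sole input, so estimators are testable from hand-built fixtures.

## Estimators

Both use d_nest = N/(L·w) and d_orang = d_nest/(p·r·t·o), with the *true*
generating values p = 1, r = 1.2 and the true detection probabilities as
*o*, so the conversion itself introduces no bias (field estimates of
these would add their own errors).

**Marked recount.** N = first detections on surveys 2…k; t = days between
first and last survey; o = mean detection probability of stages A and B
(0.925 incomplete / 0.99 complete), since new nests are nearly all fresh.

**Matrix method.** N = mean standing count per survey; o = mean across
all five stages (0.89 / 0.99). t comes from an absorbing Markov chain:
transitions are pooled over all consecutive survey pairs and transects
(a tagged nest absent from the next survey is an observed
disappearance); Q is the row-normalized transient block; t = (row sum of
(I − Q)⁻¹ for the fresh stage) × 30 days × 0.89, the correction factor
compensating under-sampling of short-lived nests. Conventions chosen
where the method description is open:

* N is the *mean* per-survey standing count (not the sum): the density
  in d_nest is a standing-crop density and t a lifetime, so their ratio
  is a production rate per snapshot.
* The fit must be given the survey schedule when a survey recorded
  nothing (the absorptions it witnessed are data; an empty survey is
  otherwise invisible in the table).
* Stages never usable as a source are deleted from the transient set
  before inversion, iteratively (a row whose only exits lead to deleted
  states becomes empty itself). If stage A is deleted the earliest
  retained stage starts the sojourn.
* If no disappearance was observed, (I − Q) is singular and the estimate
  is recorded as status `undefined` with reason `no-complete-decay` —
  never silently dropped, because conditioning on ≥1 observed decay is
  exactly what biases the method at low effort.

**Borrowed decay time.** Identical to the matrix method but with t set
to a published mean decay time. The 0.89 correction is *skipped* by
default (switchable): published values are already end-to-end mean
visibility times.

## Experiments

Replicates each draw a fresh environment, population and transect
placement from deterministically spawned seeds. Summaries report median,
IQR, the proportion of defined estimates within ±33 % of the truth, and
the count of undefined estimates.

The decline experiment surveys monthly for `4 + 12 · duration_years`
surveys: a four-survey baseline block, then three four-survey periods
per year. Within a block the marked recount uses first detections on
block surveys 2–4 with t = 90 days (persistent tagging from continuous
surveying makes the block's first survey a re-baseline); the matrix
method refits Q from the block's own transitions. A period scores 1 if
its estimate is strictly below the baseline estimate; yearly values
average three consecutive periods, with an exact two-tailed binomial
p-value against 0.5 (computed from the pmf directly). Decline runs use
complete visibility: under incomplete visibility the baseline block
inherits the missed-then-found standing-crop inflation, and even a
stable population would be flagged "declining" ~85 % of the time,
contradicting the 50 % chance level the binary coding assumes.

## What the generator does and does not emulate

The generator reproduces the study conditions: densities, movement and
construction rates, stage-wise decay with seasonal autocorrelation,
detection probabilities, tagging. It does **not** model home ranges,
habitat preference or social structure (movement is a pure random walk),
spatially autocorrelated habitat, births/immigration, dependent
non-nest-building juveniles, observer fatigue, or distance-dependent
detection within the strip. Passing tests therefore validate the
estimators under idealized mixing and stationarity; on real landscapes,
clumped habitat and ranging would add variance that these results do not
capture.

## Numerical choices and problem sizes

Durations are float32; a nest store compacts dead rows periodically
(ids are never recycled). Simulated cohorts and replicate counts used by
the test suite and the acceptance script: 10,000-nest lifetime cohorts;
50 replicates for the complete-visibility effort batch and the
incomplete-visibility bias batch (full 100 km² world); 30 replicates of
the 7-year decline design; 3 × 600 equilibrium days in a 25 km²
density-preserving world for the reuse rate; 20 random chains × 10⁵
Monte-Carlo absorptions for the fundamental-matrix oracle. These sizes
keep a full run in the ten-minute range on one core while holding
Monte-Carlo error well inside the tolerances being checked.

## Known limitations

* The altitudinal gradient's slope is a configurable stand-in (β = 0.3)
  for an unrecoverable original value; results are insensitive to it
  because it is mean-preserving.
* The seasonal walk's clamped, arithmetically asymmetric bounds shorten
  mean nest visibility by ~10 % relative to the nominal 265 days; the
  matrix method fitted on the simulation's own data absorbs this, but
  quantities derived analytically from "265 days" will sit ~10–15 %
  above what the simulation realizes.
* Single-run standing crops vary ±15 % across seeds through the
  four-type decay-mean hyper-draw and the slowly mixing seasonal walk;
  replicate averages, not single runs, are the meaningful outputs.
* One-year detection of a 5 %/year decline is information-limited: with
  ~50 newly built nests per four-survey block at the recommended effort,
  a 5 % step moves the estimate by well under one standard error, so
  year-one detection rates plateau near 0.6 regardless of estimator
  details; multi-year declines are detected reliably.
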
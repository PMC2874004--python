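"""What borrowing a nest decay time from another site does to an estimate.

Published mean orangutan nest decay times span 72 to 424 days across
sites. The matrix method divides the standing nest density by the decay
time, so substituting a borrowed value for the locally fitted one rescales
the estimate by fitted/borrowed -- an error of up to several-fold in
either direction. One equilibrium survey campaign makes the point.
"""

import numpy as np

from nestsim import (EstimatorParams, estimate_with_published_decay,
                     make_micro_world, matrix_estimate, run_survey_series)

config = make_micro_world(grid_side=2500, first_survey_day=800)  # 50 orangutans
schedule = [1, 2, 3, 4, 5, 6]
obs, transects, _ = run_survey_series(
    config, n_transects=13, transect_length=500, n_surveys=6,
    visibility="complete", seed=7)
params = EstimatorParams.for_survey(config, transects, "matrix", "complete")

fitted = matrix_estimate(obs, params, survey_indices=schedule)
print(f"truth: {config.n_orangutans} individuals")
print(f"locally fitted decay time {fitted.t_days:.0f} d "
      f"-> {fitted.estimate:.1f} individuals")
for borrowed in (72.0, 424.0):
    rec = estimate_with_published_decay(obs, borrowed, params,
                                        survey_indices=schedule)
    print(f"borrowed decay time {borrowed:.0f} d -> {rec.estimate:.1f} "
          f"individuals ({rec.estimate / config.n_orangutans:.2f}x truth)")
print("The same survey data yield estimates spanning almost an order of "
      "magnitude; site-specific decay rates matter.")
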
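"""Monitor a declining population with rolling marked-recount estimates.

Removes 5% of the remaining orangutans on the first day of each year and
surveys monthly. The first four surveys set a baseline estimate; every
later block of four surveys yields a fresh estimate coded 1 if it falls
below the baseline. The proportion of flags across replicates is the
probability the monitoring scheme would alert a manager to the decline.
A handful of small-world replicates keeps this demo quick; detection
probabilities stabilize with more replicates and more transect-km.
"""

from nestsim import ExperimentSpec, decline_experiment, make_micro_world

config = make_micro_world(grid_side=2500, first_survey_day=800)  # 50 orangutans
spec = ExperimentSpec(experiment="decline", n_replicates=4, n_transects=13,
                      transect_length_squares=500, visibility="complete",
                      decline_rate=0.05, duration_years=2, seed=11)
results = decline_experiment(spec, config)

years = results["years"]
print("per-year decline-detection proportions (marked recount vs matrix):")
print(years.pivot(index="year", columns="method", values="proportion")
      .to_string(float_format=lambda v: f"{v:.2f}"))
fails = results["failures"].iloc[0]
print(f"matrix baselines undefined (no nest fully decayed): "
      f"{fails.n_baseline_undefined} of {fails.n_replicates} replicates")
print("Marked recount flags the decline more reliably as cumulative loss "
      "grows; a stable population would be flagged ~50% of the time.")
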
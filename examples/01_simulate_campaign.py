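"""Generate a complete synthetic recruitment study.

Draws an activity log (what was done, when, with how many working hours),
the daily registration counts those activities produce under the log-normal
response-curve model with Poisson count noise, one participant record per
registrant, and census marginals for the representativeness comparison.
"""

import recruitflow as rf

config = rf.ScenarioConfig(seed=1)
dataset = rf.generate_dataset(config)

series = dataset.registrations[0]
print(f"categories            : {list(config.categories)}")
print(f"activities            : {len(dataset.activities)}")
print(f"study window          : {config.study_days} days")
print(f"registrations (total) : {series.total:.0f}")
print(f"participants          : {len(dataset.participants)}")
started = sum(p.baseline_started for p in dataset.participants)
print(f"baseline started      : {started}")
print(f"true curve            : mu={dataset.truth.mu}, sigma={dataset.truth.sigma}")
print(f"true totals/category  : "
      f"{ {c: e * config.activities_per_category for c, e in config.categories.items()} }")

# The registration series is the sum of one log-normal response curve per
# activity; its total approximates the summed true category totals (the
# curve mass outside the study window and Poisson noise account for the
# difference).
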
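"""Cohort bookkeeping: the participation funnel, withdrawal, and the
recruitment-source table.

Attrition is reported at the two funnel stages (registered -> started the
baseline questionnaire -> finalized it); withdrawal uses baseline starters
as its denominator.
"""

import recruitflow as rf

dataset = rf.generate_dataset(rf.ScenarioConfig(seed=1))
participants = dataset.participants

funnel = rf.funnel_counts(participants)
rate_a, rate_b = rf.attrition_rates(funnel)
print(f"registered {funnel.registered} -> started {funnel.started} "
      f"-> finalized {funnel.finalized}")
print(f"attrition registration->started : {rf.round_half_up(rate_a)}%")
print(f"attrition started->finalized    : {rf.round_half_up(rate_b)}%")
print(f"withdrawal (of starters)        : "
      f"{rf.round_half_up(rf.withdrawal_rate(participants)['overall'])}%")
print()

table = rf.source_table(participants)
print("How participants found out about the survey:")
print(table[["source", "n", "pct"]].to_string(
    index=False, float_format=lambda v: f"{v:.2f}"))

# Percentages are row shares of all participants; the generator draws
# sources from the configured marginal distribution, so large samples
# reproduce it closely.
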
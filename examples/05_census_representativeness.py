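"""Compare the recruited sample with the city's census distribution.

Goodness-of-fit chi-square of the sample's gender and age-class counts
against census shares, with Cohen's w = sqrt(chi2/n) as the effect size.
The default scenario recruits a younger crowd than the census population:
expect a clearly non-negligible age effect (w around 0.3) but only a
trivial gender one (w well under 0.1) — at a few thousand participants even
a trivial shift can reach p < .05, which is why the effect size is reported
alongside the test.
"""

import recruitflow as rf

dataset = rf.generate_dataset(rf.ScenarioConfig(seed=1))
census = dataset.census[0]
frame = rf.participants_frame(dataset.participants)

for margin, column in (("gender", "gender"), ("age", "age_class")):
    shares = census.margin_shares(margin)
    counts = frame[frame[column].isin(shares)][column].value_counts().to_dict()
    res = rf.census_comparison(counts, census, margin)
    verdict = "representative" if res.p > 0.05 else "NOT representative"
    print(f"{margin:>6}: chi2={res.chi2:8.2f} df={res.df} p={res.p:.3g} "
          f"w={res.effect_size:.3f}  -> {verdict} (n={res.n})")

# Cohen's w around 0.1 is conventionally a small discrepancy, 0.3 medium,
# 0.5 large.
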
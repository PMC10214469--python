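"""Descriptive statistics per trait, environment and location.

Min/max/mean and sample standard deviation are computed at plot level,
the layout conventional for multi-environment trial reports.
"""

from metstress import describe_traits, simulate_met

dataset, _ = simulate_met(seed=1)
summaries = describe_traits(dataset)

sy = summaries[summaries["trait"] == "SY"].round(1)
print("seed yield (g/plot):")
print(sy.to_string(index=False))
print()
print("Within each location the mean drops from OE through HSE to HDSE: "
      "the two stress treatments depress yield, combined heat-drought "
      "most strongly.")
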
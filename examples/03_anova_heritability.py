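"""Pooled factorial ANOVA, variance components and heritability.

The pooled model decomposes seed yield over location, year, environment,
genotype and their interactions (sequential SS, F against the residual).
Method-of-moments variance components from the expected mean squares give
the entry-mean broad-sense heritability.
"""

from metstress import (
    broad_sense_heritability, estimate_variance_components,
    fit_factorial_anova, simulate_met,
)

dataset, _ = simulate_met(seed=1)
table = fit_factorial_anova(dataset, "SY")
print(table.table.round(2).to_string(index=False))
print()

vc = estimate_variance_components(table, dataset.design)
print("variance components (g^2):",
      {k: round(v, 1) for k, v in vc.as_dict().items()})
h2 = broad_sense_heritability(vc, dataset.design)
print(f"broad-sense heritability H^2 = {h2.h2:.1f}%")
print()
print("A significant Env:Gen term means genotypes respond differently to "
      "stress — the premise of index-based selection; H^2 is the share of "
      "entry-mean variance that is genotypic.")
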
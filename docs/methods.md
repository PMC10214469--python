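# Methods

## Data model

The canonical exchange format is a long ("tidy") CSV with one row per plot
(genotype × location × year × environment × replicate, with the incomplete
block as design metadata) and one column per trait. Eleven traits are
recognised: DFF (days to 50% flowering), DM (days to maturity), PH (plant
height, cm), NT (tillers/plant), SL (spike length, cm), NSS
(spikelets/spike), NGS (grains/spike), TKW (kernel weight, g), BY
(biological yield, g), HI (harvest index, %), SY (seed yield, g/plot).
TKW is stored as an opaque weight in grams and never rescaled, since
published values in the low single digits suggest a 100-kernel rather than
1000-kernel weight. Years are opaque season labels ("2020-21"), never
parsed as integers. Missing trait values propagate as missing and are
never imputed; each operation states its own missing-data policy
(pairwise-complete correlations, arm-complete genotypes for contrasts,
balance required for ANOVA). HI is validated against 100·SY/BY when all
three are present; a deviation above 0.5 percentage points earns a warning
but the stored value is kept, because HI is recorded as a measured trait
even though it is defined as a ratio.

## ANOVA

All factors are treated as fixed: OLS with sequential (Type-I) sums of
squares in the conventional term order, every F against the residual mean
square, and stars at 0.05/0.01/0.001. This reproduces the mean-squares
layout of classical multi-environment trial reports; a REML mixed model
would not yield a SS decomposition. Balanced data make the main-effect SS
order-invariant; unbalanced data are rejected outright rather than
silently switching to Type-III. The alpha-lattice blocks enter as fixed
`Block(Rep)` effects (intra-block analysis, no inter-block information
recovery); with two blocks per replicate this term carries 2 df. Terms
omitted from the requested list are absorbed by the highest-order
interaction that spans them, which keeps the printed df internally
consistent (they always sum to N − 1) even when the term list is shorter
than the full factorial.

The "random factor" role of locations, years and environments is honoured
through the expected-mean-square step. For the balanced pooled model with
l locations, y years, e environments and r replicates:

```
E[MS_GL]  = σ²_ε + y·e·r·σ²_GL          (GY, GE analogous)
E[MS_Gen] = σ²_ε + y·e·r·σ²_GL + l·e·r·σ²_GY + l·y·r·σ²_GE + l·y·e·r·σ²_G
E[MS_res] = σ²_ε
```

solved by method of moments; negative solutions are truncated to zero and
flagged. Entry-mean broad-sense heritability is

```
H² = σ²_G / (σ²_G + σ²_GL/l + σ²_GY/y + σ²_GE/e + σ²_ε/(l·y·e·r)) × 100,
```

clamped to [0, 100]. The published tables print a heritability row without
stating a formula, so this H² is a documented convention of the package,
not a reproduction.

Post-hoc mean separation offers LSD (t·√(2·MS/n)) and Tukey HSD
(q·√(MS/n)) with a strict-inequality significance rule and a compact
letter display built by the insert-and-absorb sweep.

## Stress indices

STI, SSI, MP, TOL and MSTI follow their standard definitions (see the
README table). GMP = √(Yp·Ys) is included as a sixth index because the
discussion of such trials routinely invokes it; its formula is a field
convention and it is marked `"convention"` in the table metadata. Yp/Ys
are genotype means per location with years and replicates pooled;
population means are unweighted over the genotypes with both arms
observed. Negative TOL (yield gain under stress) is flagged, never
clamped. Ties in ranking break by higher Ys, then genotype id. Report
tables round half-away-from-zero at the printed precisions (SY/MP/TOL/GMP
integer, STI/SSI two decimals, MSTI one); internal computation always
keeps full precision. The `SY(g)` column of the report prints Yp and is
labelled as such, because the corresponding published column is not
internally consistent with any printed Yp/Ys pair and cannot be
re-derived.

## Percent reductions

Reductions are computed on genotype × environment pooled means — never by
pairing arbitrary replicates across environments — and summarised across
genotypes as the unweighted mean of per-genotype percent reductions. This
mean-of-ratios convention is a documented contract (a regression test
pins it): on heterogeneous data it differs from the ratio of mean yields,
and published per-location summary rows are consistent with per-genotype
averaging.

## Associations

The unit of analysis is the genotype mean within an environment, pooled
over locations and years (n = number of genotypes); plot-level analysis
is available behind `unit="plot"`. Pearson r with two-sided t-test
p-values (df = n − 2), stars at 0.05/0.01, no multiple-testing correction
across the 55 pairs — mirroring the reporting convention of such trials.
Single-predictor OLS regressions of seed yield are ranked by R², which
equals the squared Pearson r of the pair by construction.

## Synthetic trials

The generator emulates the study layout: 34 genotypes × 2 locations × 2
seasons × 3 environments × 2 replicates = 816 plots, with genotypes
re-randomised into 2 incomplete blocks per replicate (re-randomisation per
cell is also what keeps the genotype and block design columns from being
exactly collinear). A plot value is

```
value = m[i, env] · (μ_loc + year + g_i + gl + gy + ge + block + ε)
```

for magnitude traits, with Gaussian effects and noise and truncation at
zero (a warning fires above a 1% truncation rate); phenology (DFF and the
DFF→maturity gap that defines DM, keeping DM ≥ DFF) instead receives
additive shifts, so large relative yield losses coexist with modest
phenology advances. HI is derived as 100·SY/BY with SY capped at BY.
Genotype effects are coupled across traits by factor loadings: the seed
yield latent loads 0.75 on grains per spike and 0.25 on kernel weight,
and biomass shares part of the yield latent, which makes NGS and TKW the
leading yield predictors, as observed in real trials.

Environment multipliers default to OE 1.0, HSE 0.80, HDSE 0.64, matching
published mean seed-yield reductions of ≈20% and ≈36%; per-trait
multipliers and the phenology shifts likewise follow the published
per-trait mean reductions, and optimum-environment means per location
follow the published descriptive statistics. A configurable subset of
"true tolerant" genotypes (default 5) keeps only `1 − tolerance` of each
stress penalty (default tolerance 0.8, i.e. a 4% loss under HSE where the
population loses 20%); the remaining genotypes' penalty is scaled up so
the population-mean multiplier — and hence the expected stress intensity —
equals the configured value exactly.

Variance components for seed yield default to σ_G = 30, σ_GL = σ_GY = 15,
σ_GE = 25, σ_ε = 60 g/plot. These were sized by a power calculation so
that the tolerance signal is detectable at the trial's replication level:
top-5-by-STI then recovers ≥3 of the 5 planted tolerants in ≈100% of runs
under the combined heat–drought contrast (the package's end-to-end
recovery check) and ≈90% under heat alone. This deliberately puts the
baseline genotypic yield variance below the plot-level spread of the
published descriptive tables — with a landrace-panel-sized genotypic
variance, STI ranking is dominated by yield potential and planted
tolerance would be unrecoverable by design; the trait models expose every
knob for users who want the wider regime.

Because stress acts multiplicatively, the nominal σ² parameters are not
what the pooled ANOVA estimates. The ground-truth object therefore
computes *effective* components from the noise-free expected-value
surface: its balanced decomposition gives surface mean squares, and the
same EMS algebra maps them to the estimands (e.g. σ²_G,eff =
(MS̃_G − MS̃_GL − MS̃_GY − MS̃_GE)/(l·y·e)). Recovery tests compare
estimates against these realised values; at the defaults the 200-seed
median of σ̂²_G/σ²_G,eff is within a few percent of 1.

One seed governs all draws: the master seed sequence spawns one stream
for genotype-level effects shared across locations and one sub-stream per
location, so a location can be regenerated without disturbing the others.

### What the generator does and does not emulate

It reproduces the design (factor structure, incomplete blocks,
replication), the stress-response magnitudes, trait coupling and a
ground-truth tolerant set. It does not simulate weather processes,
spatial field trends, non-Gaussian trait distributions, or
genotype-specific phenology–stress interactions (escape through
earliness). Passing recovery tests therefore demonstrates that the
estimators and the selection machinery are correct and calibrated under
the stated generative model — not that real trials of this size would
identify tolerant germplasm with the same reliability.

## Numerical choices

- Sample (n−1) standard deviations in descriptive statistics.
- Sequential SS conservation is tested to 1e-8 relative; index-table
  oracle equivalence to 1e-12.
- Degenerate inputs: constant responses report missing F; zero stress
  intensity (stress yields ≥ optimum) is a hard error for SSI and yield
  summaries; a genotype with Yp = 0 gets a missing SSI while its other
  indices are computed; zero-variance traits have their correlations
  reported missing with a warning.
- Significance boundaries are strict (`p < α`, `|diff| > critical`).
- Rounding for report tables is half-away-from-zero (printed-table
  convention), not banker's rounding.

## Problem sizes

The test suite and the acceptance script run the pooled ANOVA on the full
816-plot layout; stochastic checks use 200 seeds for variance-component
and tolerant recovery, 40 seeds for stress-intensity and reduction means,
1000 permutations for F-test calibration and 1000 pairs for star
calibration — sizes at which every Monte-Carlo interval in the checks is
a ≥3σ margin.
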
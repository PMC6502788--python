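# emfkit

Biodiversity–ecosystem multifunctionality (BEMF) analysis for plot-based
community surveys, with a focus on comparing **species richness (SR)**
against **functional richness (FRic)** as drivers of the simultaneous
provision of multiple ecosystem functions (EMF). It is written for
community ecologists analysing plot × species, species × trait and
plot × function tables — the standard data layout of forest and grassland
diversity–function studies.

## What it computes

**Diversity.** SR is the number of species present in a plot. FRic is the
volume of the convex hull spanned by the plot's species in multivariate
trait space (by default SLA, WD and LA, z-scored across the species pool);
plots with fewer than `dims + 1` affinely independent trait points are
flagged undefined rather than zeroed. Trait-derivation helpers implement
the conifer needle-area formula LA = (2π√3⁄9)·d·L, SLA = leaf area / dry
mass, and WD = dry mass / volume.

**Averaging EMF.** Each function column is standardized,
Z_pf = (y_pf − ȳ_f)/s_f, and EMF_p = mean_f Z_pf.

**Multiple-threshold analysis.** For each threshold t = 1…99 % of a
function's maximum (the mean of its top five observed values), count the
functions each plot pushes past t and fit OLS: count_p = a_t + b_t·D_p for
a diversity metric D. The slope-vs-threshold curve is summarized by

- *T_min*, *T_max* — the range of thresholds where diversity has a
  significantly positive effect,
- *T_mde* — the threshold of the maximum diversity effect (argmax b_t),
- *R_mde* — the slope at T_mde (functions gained per unit diversity),
- *P_mde* = 100·R_mde / (F / range(D)) — R_mde as a percentage of the
  steepest slope possible given F functions over the observed diversity
  range.

**Null-model SES.** Trait rows are shuffled across species labels
(richness-controlled null: community composition, and hence SR, is fixed;
trait multisets are conserved). For each metric–target pair the Pearson
correlation r across plots is standardized as

    SES = (r_obs − mean(r_null)) / sd(r_null),

giving a Table-of-SES shaped (SLA, WD, LA, FRic) × (each function, EMF).

**Driver attribution.** Per-function OLS of each function on SR and FRic;
a multivariate linear model of EMF on SR, FRic, MAT, MAP and soil pH with
standardized coefficients; and column-order-invariant permutation
importance from a random-forest regression.

**Synthetic data.** `gen_dataset(SimConfig(...))` draws plot communities
with a richness gradient, a monodominant species holding a configurable
share of stems (default 90 %), geometric-series rank abundances, correlated
lognormal traits, and functions generated as linear effects of SR/FRic plus
Gaussian noise — so every planted effect is exactly what the analysis chain
should recover.

## Worked example

```python
import emfkit as ek

data = ek.gen_dataset(ek.SimConfig(), seed=1)      # 58 plots, 54 species
div  = ek.diversity_table(data.community, data.traits)
emf  = ek.averaging_emf(data.functions)

res = ek.ThresholdAnalysis(data.functions, div["FRic"], "FRic").fit()
print(res.summary())
```

```
Multiple-threshold multifunctionality analysis
  diversity metric : FRic
  plots            : 58
  functions        : 8
  diversity range  : 27.79
  T_min            : 22%
  T_max            : 91%
  T_mde            : 77%
  R_mde            : 0.1311 functions per unit FRic
  P_mde            : 45.54%
```

Read: FRic has a significantly positive effect on the number of functions
sustained at every threshold from 22 % to 91 % of maximum function
performance; the effect peaks at the 77 % threshold, where one extra unit
of FRic adds 0.13 functions — 45.5 % of the steepest effect possible over
this FRic gradient. The same object for SR, plus
`ek.standardized_multiregression`, `ek.rf_importance` and
`ek.SESAnalysis(...).fit()`, complete the driver-attribution picture.

A command-line interface mirrors the library:

```bash
emf simulate --fixture paper_shape --out data/
emf diversity --community data/community.csv --traits data/traits.csv --out div.csv
emf average   --functions data/functions.csv --out emf.csv
emf thresholds --functions data/functions.csv --diversity div.csv \
               --metric FRic --out curve.csv --indices indices.json
emf ses       --community data/community.csv --traits data/traits.csv \
              --functions data/functions.csv --n-null 999 --seed 42 --out ses.csv
emf drivers   --functions data/functions.csv --diversity div.csv \
              --env data/environment.csv --emf emf.csv --seed 42 --out drivers/
```

All commands are byte-deterministic for a fixed seed.

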
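# Methods

## Scope and data model

The package analyses plot-level biodiversity–ecosystem-multifunctionality
(BEMF) relationships from four aligned tables: plot × species abundance,
species × trait, plot × ecosystem function, and (optionally) plot ×
environment. Identifiers are opaque strings matched exactly; the canonical
plot order is the community table's. Missing function values are a hard
error by default, with an explicit row-drop option; imputation is never
offered, because silently manufactured function values would propagate into
every downstream index.

## Functional richness

FRic for a plot is the convex-hull volume of the trait points of the
species present (presence-based; abundances are deliberately ignored, as
FRic measures the extent of occupied trait space, not its occupancy
density). Hulls are computed with Qhull via `scipy.spatial.ConvexHull`
after removing exact duplicate points, which hull libraries reject.

Numerical choices:

- **Standardization.** Traits are z-scored (sample sd, n−1) across the
  species pool before hull construction, so no single trait's units
  dominate the volume. `range` scaling and `none` are exposed as options;
  the choice is recorded in the `FRicOptions` used.
- **Degenerate plots.** A plot with fewer than `dims + 1` distinct trait
  points, or with affinely dependent points (Qhull error), has no
  full-dimensional hull. The default policy flags it *undefined* (NaN plus
  a `FRic_defined = False` flag) and downstream regressions drop it with a
  warning; a `zero` policy exists for users who prefer FRic = 0. Reducing
  dimensionality per plot was rejected: per-plot dimensionalities make
  volumes incomparable across plots.
- **Dimension reduction.** An optional projection onto leading principal
  components (`reduce_dims`) is available for trait sets too large for the
  richness at hand; it is off by default since the standard three traits
  (SLA, WD, LA) are all numeric and low-dimensional.
- In one dimension the hull volume is the range (max − min), computed
  directly.

Trait utilities implement the needle leaf-area formula
LA = (2π√3/9)·d·L (cylinder approximation for conifer needles, d and L in
mm, LA in mm²), SLA = leaf area / dry mass (mm²·mg⁻¹) and WD = dry mass /
volume (g·cm⁻³), with hard errors on non-positive inputs.

## Multifunctionality indices

**Averaging index.** Function columns are standardized to mean 0 and
sample sd 1 (n−1 denominator; a zero-variance column is an error naming the
function) and averaged within plots. The index is invariant under positive
affine transforms of any function column and has mean 0 across plots by
construction.

**Multiple-threshold analysis.** A function's *maximum* is the mean of its
top five observed values (values tied with the fifth-largest are all
included; with fewer than five plots, all values are used), which blunts
single-plot outliers. For each integer threshold t in 1…99 %, the per-plot
count of functions with value ≥ t % of their maximum ("exceed" is ≥, so
ties meet the threshold — stated explicitly for bit-reproducibility) is
regressed on the diversity metric by OLS. Slopes, standard errors,
two-sided p-values and 95 % confidence intervals use the t-distribution
with n − 2 df; the curve reports both SE and CI columns. Two exact special
cases: a count constant across plots has slope exactly 0 and p defined as 1
(no evidence, never NaN); a perfect non-constant fit has SE 0 and p 0.
Functions whose maximum is non-positive have no meaningful
percent-of-maximum and are excluded from counts with a warning.

OLS (rather than a count GLM) is used for the per-threshold fits, matching
the fitted-values presentation standard in the multiple-threshold
literature; at F ≤ 8 functions the counts are far from Poisson asymptotics
and the OLS slope is the quantity the summary indices are defined on. The
per-threshold fits are computed by closed-form normal equations vectorized
over thresholds and are cross-checked against `statsmodels.OLS` in the test
suite.

**Summary indices.** With slope curve b_t and p-values p_t:

- T_mde = argmax_t b_t (first maximum if tied);
- R_mde = b_{T_mde};
- T_min = smallest t with b_t > 0 and p_t < 0.05;
- T_max = smallest t > T_mde with p_t ≥ 0.05; if significance persists to
  t = 99, the largest significant t. This operationalizes "the threshold
  beyond which the slope declines and is no longer distinguishable from
  zero" while remaining total;
- P_mde = 100 · R_mde / (F / range(D)): the realized maximum effect as a
  percentage of the steepest possible slope, i.e. the slope that would
  carry counts from 0 to all F functions across the observed diversity
  range (max − min across analysed plots). This definition is emitted in
  the CLI's `indices.json` metadata so results are auditable.

All five indices are reported as undefined when no threshold shows a
significantly positive slope (α = 0.05 throughout).

## Null model and SES

The richness-controlled null permutes whole trait rows across species
labels. Because community composition is untouched, every plot's SR is
fixed; because rows travel together, the trait covariance structure of the
pool is preserved while the assignment of trait syndromes to species — and
with it FRic and community-mean traits — is randomized. Per-trait
independent shuffling would additionally destroy trait covariance and is
not the default.

The statistic standardized in the SES table is the **Pearson correlation**
between a per-plot metric (community mean of each trait over the species
present, and FRic) and a per-plot target (each function, and EMF). A
correlation is scale-free, so SES values are comparable across functions
measured in different units; the statistic's identity is recorded in the
results object. SES = (obs − null mean)/null sd with the null sd computed
with n−1; a zero-spread ensemble yields an undefined (NaN) SES rather than
a division by zero. Default ensemble size is 999 shuffles; all draws flow
from a single seeded generator, so (seed, n_null) fully determine the
ensemble. The full table shares one ensemble across cells, which is
statistically equivalent to per-cell ensembles and much cheaper.

Under exchangeable traits (no true trait–function structure) the SES is
approximately standard normal; with a finite ensemble its sd is mildly
inflated (t-like, factor ≈ √((m−1)/(m−3)) for ensemble size m). The
calibration test in the acceptance suite uses 200 independent null datasets
with 60-shuffle ensembles and checks mean within ±0.2 and sd within
[0.7, 1.3].

## Driver attribution

- **Per-function regressions** use `statsmodels` OLS; the table reports
  Pearson r, R², and raw p per metric, plus a Holm-adjusted column — raw
  p-values are the primary presentation (matching common practice for
  per-function tables), the Holm column is included for honesty about the
  8-function family.
- **Standardized multivariate model.** EMF on SR, FRic, MAT, MAP, soil pH.
  Standardized coefficients are β·sd(x)/sd(y), identical to refitting on
  z-scored variables, hence invariant to affine rescaling of any predictor.
  Rank-deficient designs raise an error naming the aliased predictors.
- **Random-forest importance** is *permutation* importance (mean increase
  in training MSE when one predictor's values are shuffled), chosen over
  impurity importance for its robustness to scale and cardinality biases.
  Defaults: 1000 trees, 10 shuffle repeats, mandatory seed. Predictors are
  canonicalised by sorted name before fitting and each column's shuffles
  are seeded from (seed, hash of the column name), so importances are
  byte-reproducible and invariant to the order predictor columns are
  supplied in. Raw importances of pure-noise predictors can be slightly
  negative by sampling noise; the reported `importance` is floored at 0
  and the unfloored value kept as `raw_importance`. Ranks break ties by
  predictor name.

## Synthetic data generator

The generator emulates the *statistical* structure of a monodominant
subtropical secondary-forest survey, not its biogeochemistry: 58 plots, a
54-species woody pool, 3 traits, 8 functions (PN, PP, SHN, SAP, STN, STP,
STC, WPB), a uniform richness gradient (default 4–18 species per plot, so
3-D hulls are defined), and one dominant species present in every plot
holding 90 % of stems, with subordinates following a geometric-series
rank-abundance distribution (ratio 0.5) at 100 stems per plot nominal.
Traits are correlated lognormal (log-scale sd 0.3/0.15/0.6 for SLA/WD/LA,
an acquisitive–conservative SLA–WD correlation of −0.4), guaranteeing
positivity. Environment covariates are uniform over the study envelope
(MAT 15.7–18.2 °C, MAP 954–1202 mm, pH 5.5–7.0) and enter the functions
centred.

Functions are generated directly on the realized diversity metrics:
f_p = base_f + effect_sr[f]·SR_p + effect_fric[f]·FRic_p + env terms +
N(0, noise_sd[f]), with noise sd 1 in function units. The default
configuration plants a moderate FRic effect (0.3 functions per FRic unit)
on the three nutrient functions (PP, SAP, STN) and none elsewhere — the
qualitative pattern of a monodominant forest where biomass is insensitive
to richness; SR–function associations then arise only through the natural
SR–FRic correlation, as in real communities. Canned fixtures: `tiny`
(4 plots × 5 species smoke test), `paper_shape` (defaults), `null` (no
planted effects; drives the SES calibration), `strong_fric` (effect 0.5 on
all eight functions, zero direct SR effect; drives the recovery study).

What passing tests on these data do and do not show: the generator
produces linear, homoscedastic diversity–function links with Gaussian
noise and no spatial autocorrelation, measurement error in traits,
phylogenetic structure, or function trade-offs. Recovery results therefore
certify the *analysis chain* (indices, null model, attribution), not the
robustness of the method to real-data pathologies.

## Problem sizes and determinism

Simulation-based checks use 200 null datasets with 60-shuffle ensembles
for SES calibration and 100 replicate datasets with 300-tree forests for
the effect-recovery study; with n = 58 plots and 5 predictors, importance
ranks stabilize well below the 1000-tree default, so the smaller forests
measure the same ranking. The acceptance script uses the full defaults
(999-equivalent: 199 shuffles for its single SES table, 1000 trees). All
randomness flows from explicit seeds through `numpy.random.Generator`; no
global random state is touched, and CLI outputs are byte-identical across
re-runs with the same seed.

## Known limitations

- The convex-hull FRic inherits Qhull's behaviour for near-degenerate
  point sets; plots flagged undefined are excluded from regressions rather
  than patched.
- T_max's definition depends on the chosen operationalization when the
  slope curve is multimodal; the definition used is stated above and in
  the output metadata.
- The SES table standardizes correlations; analyses that standardize
  regression slopes or raw metric values would need a custom statistic via
  `ses()`, which accepts any callable.
- Partial least squares regression coefficients are not provided; the
  standardized OLS coefficients are the supported multivariate output.
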
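# Methods

This note records the statistical procedures `microtraj` implements, the
defaults it fixes where a choice had to be made, what the synthetic cohort
generator does and does not emulate, and the package's known limitations.

## Data model

The pipeline starts from three tables: a species-level relative-abundance
profile (samples × species, percent scale, per-sample sums ≤ 100, species
named in the MetaPhlAn clade dialect), a per-sample metadata record
(rat, group, time point TP1–TP5, body weight in g, clinical arthritis
score, serum cytokines IL-17/IL-1β/TNF-α/IL-6/IFN-γ/IL-2 in pg/mL), and a
KO relative-abundance table with a module→KO membership map. Upstream
steps — sequencing, read QC, host removal, taxonomic and functional
profiling — are out of scope; the pipeline consumes profile tables.

A single scale-aware pseudocount is used wherever zeros meet a logarithm
or a denominator: **ε = half the smallest nonzero value of the table at
hand**. This keeps the pseudocount proportionate to the detection limit of
the specific table rather than hard-coding a scale.

## Preprocessing

- **Prevalence filter.** A rat *presents* a species if its abundance is
  positive in at least one of the rat's longitudinal samples; species
  presenting in fewer than 5% of rats are removed. Counting per rat rather
  than per sample reflects that the replication unit of the design is the
  animal.
- **Normalization for regression.** `v′ = log10(v + ε)`, then per-species
  z-scores with the population (n-denominator) standard deviation.
  Zero-variance species map to all-zero columns. The population/sample SD
  choice is immaterial statistically but is fixed for exact
  reproducibility.

## Plane-distance trajectories

One joint PCoA (classical scaling: eigendecomposition of the
double-centered −½D² matrix, coordinates scaled by √eigenvalue) is
computed over *all* samples, groups and time points, so that distances
from any sample to both planes live in one shared coordinate system.
Axes with eigenvalue ≤ 1e-8 × the largest — including all negative axes
arising from the non-Euclidean Bray-Curtis metric — are dropped; no
Cailliez/Lingoes correction is applied since only the first three
coordinates are used downstream.

At each time point, the healthy plane is fitted to the control-group
samples and the disease plane to the untreated model-group samples, in the
first three coordinates, by **orthogonal (total) least squares**: centroid
= mean point, normal = right singular vector with smallest singular value,
sign canonicalized (first nonzero component positive) for reproducible
serialization. Orthogonal fitting is the geometry consistent with
measuring *Euclidean* point-to-plane distances afterwards; a
regression-style fit (third coordinate on the first two) would minimize a
different residual. Distances are |(x − centroid)·normal|.

Paired t tests compare a group's HP vs DP distances at a time point.
Degenerate inputs are reported, not raised: all-zero differences give
(t=0, p=1); zero-variance nonzero-mean differences give p=0 with a
degeneracy flag.

The association between arthritis score and plane distance is the
semi-partial Spearman correlation below, with weight and group as
covariates, covariates removed from the *distance* variable.

## Non-negative elastic net and consensus selection

The solver minimizes

    (1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)‖β‖²₂/2)   s.t. β ≥ 0

by cyclic coordinate descent on centered data with a projected (one-sided)
soft-threshold update, Gram-matrix working quantities, and warm-started
descending-λ paths (numba-compiled). Convergence: max coefficient change
< 1e-7 in a sweep, capped at 1e5 sweeps with a non-convergence flag. The
per-sweep objective is non-increasing (asserted in tests). The
nonnegativity constraint encodes the modelling decision that candidate
markers are species whose abundance *rises* with the arthritis score.

Selection procedure: for each of 10 repeats, samples are shuffled into 5
folds; for each fold, λ is chosen on the training portion by an inner
5-fold CV over 100 log-spaced values from λ_max (the smallest λ with an
all-zero solution; α floored at 1e-3 in its computation) down four
decades, by the CV-minimum rule with ties broken toward the larger λ; one
model is then fitted on that training portion — 50 models in total.
Models with fewer than 5 nonzero coefficients are discarded; a species is
selected iff nonzero in strictly more than 25 retained models. α defaults
to 0.5 and is exposed as a parameter. The CV-minimum rule (rather than
1-SE) and the strict >25 reading are fixed, documented choices.

## Fold-change consistency rule

`value(rat, s, tp) = (a + ε) / (mean over control rats at tp of a + ε)`,
then `FC(rat, s, tp) = log10(value(rat, s, tp) / value(rat, s, TP1))`.
The reference statistic is the arithmetic mean (median available). A
(species, group, time point) cell is significant iff strictly more than
80% of the group's rats have |FC| > log10(16) ≈ 1.20 *and* all passing
rats share one sign; the shared sign is the call's direction.
"Consistency" is interpreted within a single contrast (one time point vs
baseline), matching how the calls are tabulated per time point. Both
inequalities are strict. Under per-rat abundance noise this rule is
deliberately conservative: it trades recall for specificity, and recovery
of planted shifts is complete only as noise → 0 (verified in tests).

## Semi-partial Spearman correlation

All variables are rank-transformed (average ranks on ties; dummy-coded
group indicators are ranked like any column). Covariate ranks are
regressed out of the **abundance** ranks by least squares with intercept;
the residuals are Pearson-correlated with the outcome ranks. Removing
covariates from one side only (a part correlation) answers "what does the
microbe add beyond weight/group/score"; the adjusted side is exposed as a
parameter. p-values use the t approximation with df = n − k − 2 for k
covariate columns. Constant covariates are collinear with the intercept
and are dropped (they remove nothing); genuinely rank-deficient covariate
sets raise. Zero-variance x or y yields a flagged degenerate result.

Outlier removal precedes adjustment and is applied pairwise per
(abundance, target) pair: Tukey fences at 1.5 × IQR beyond the quartiles
(linear-interpolation percentiles), per variable, removing the pair if
either member is outside; with fewer than 8 pairs no removal is attempted.
No multiple-testing correction is applied by default; Benjamini-Hochberg
q-values are available as an option.

## KEGG module statistics

Module abundance is the mean over member KOs present in the profile (sum
available); modules with no present member are dropped with a warning.
Per-KO two-sample tests report the classic Wilcoxon W (rank sum of the
first group): exact p by enumeration when n₁+n₂ ≤ 12 without ties, else
the normal approximation with tie and continuity corrections. Module
log₂ fold changes are `log2((mean at TP5 + ε)/(mean at TP1 + ε))` per
group; modules with zero mass at both time points in a group are NaN
there, and an all-groups-present filter is available for reporting. How
KO-level statistics combine into module-level "differentially enriched"
calls is left to the caller; both levels are reported.

## Synthetic cohort generator

The generator emulates the study design: 4 groups — healthy controls
(first label), untreated disease model (second), treated arms (rest) — of
7 rats each, sampled at 5 time points, with 200 species. All randomness
derives from one seed, split into independent streams per output table;
identical configs reproduce bit-identical tables.

**Community.** Per-species baseline log₁₀ abundances are normal (sd 1.2);
per-sample log-scale noise sd 0.5; samples are closed to 100%. A drift set
of 40 species moves linearly in log abundance across time in the model
group, reaching ±2 log₁₀ units (≈ 100-fold) at the final time point —
chosen to match the >16-fold per-species changes the fold-change rule is
built around. Treated groups experience (1 − reversion) × the drift
(reversion 0.7 by default). Disease-*enriched* species start
`drift_magnitude` below typical abundance (pathobiont bloom from rarity)
and disease-*depleted* species start 1 log₁₀ above typical (collapse of
dominant commensals); this mirrors the biology of arthritis dysbiosis and
keeps the compositional closure shift small enough that planted fold
changes survive renormalization. Drift multipliers vary per rat:
sd 0.1 on the log scale within the untreated model (disease progresses
consistently) and sd 0.55 within treated arms (treatment response varies
across animals). The response variability is what couples an individual
animal's community position to its clinical score within a group; keeping
the model group compact prevents the fitted disease plane from absorbing
the drift direction.

**Clinical score.** For disease and treated animals,
`score = clip(baseline + Σ w·z + noise, 0, 16)` where z are cohort-wide
z-scores of the log abundances of 5 planted signal species (a subset of
the drift set, all drifting upward so the non-negative regression can see
them) with weight 1.0 each and noise sd 0.5. Controls are pinned at 0 —
and the default baseline of 0 makes that pin consistent with the formula:
unimmunized animals (and everyone at day 0) sit at the score floor the
linear-plus-clip model itself predicts. An inconsistent pin would inject a
group-structured residual that any disease-enriched species genuinely
explains, contaminating selection with confounded "false" positives.

**Cytokines and weight.** Cytokines are log-normal around configurable
baselines (noise sd 0.25 natural-log units) with multiplicative couplings
`exp(sign · strength · z_species)` for configured (species, cytokine)
pairs; defaults couple the planted species to IL-17, IL-6, TNF-α (+0.8)
and IL-2 (−0.6). Weight grows 25 g per time step from 60 g minus 1.5 g per
score unit, noise sd 2 g.

**KO table.** KO baselines are log-normal (sd 1 log₁₀), per-sample noise
sd 0.2, rows closed to 100. Planted shifts multiply the member KOs of a
module in one (group, time point) cell — defaults: one module 4× up and
one 4× down in the model group at the final time point.

**Scenarios.** `SimConfig()` is the full study emulation used for
trajectory, fold-change, correlation and KEGG tests. For selection
recovery, `SimConfig.planted_signal()` confines the drift to the 5 planted
species so the remaining 195 are exchangeable noise and a false selection
is unambiguous; in the full cohort the co-drifting species are *genuinely*
disease-associated, so "false positive" is not a meaningful notion there.

**What the generator does not emulate** — and hence what passing recovery
tests do not establish for real data: sequencing and profiling error,
compositional correlation structure beyond closure, phylogenetic
relatedness between species, non-linear or lagged score dynamics,
rat-specific baseline microbiomes (individuality enters only through the
drift multipliers), cage effects, and missing samples. Recovery results
quantify the *procedures* under a known generative model, not expected
performance on any particular real cohort.

## Numerical choices and degenerate inputs

- Bray-Curtis of two all-zero samples is defined as 0; pairs are otherwise
  in [0, 1] with exact symmetry enforced.
- PCoA reduces k with a warning when fewer positive axes exist; an
  asymmetric or non-finite distance matrix raises.
- Plane fitting requires ≥ 3 points spanning ≥ 2 dimensions (relative
  second-singular-value test at 1e-10); collinear sets raise with a named
  degeneracy.
- λ-grid ties in inner CV resolve to the larger penalty (sparser model).
- Zero-variance guards: constant species columns z-score to 0 (tested
  against the one-ulp rounding of means of identical floats); constant
  correlation inputs flag degenerate results rather than raising.
- Problem sizes in tests and the acceptance script (full 140-sample
  cohorts, 20-seed recovery sweeps) were chosen so the complete suite runs
  in well under a minute after JIT compilation, as the package's own
  default study conditions.

## Known limitations

- The elastic-net path uses full cyclic sweeps (no active-set shortcut);
  ample for hundreds of species, not tuned for tens of thousands of
  features.
- Plane distances use only the first three principal coordinates by
  construction; communities whose disease axis lies mainly in higher
  coordinates would be invisible to the HP/DP summary.
- The semi-partial correlation's p-value is the large-sample t
  approximation; no permutation option is built in (tests validate the
  coefficient against independent oracles and permutation nulls).
- No phylogenetically informed distance (e.g. UniFrac) and no
  compositionally aware correlation (e.g. SparCC) are provided; both are
  deliberate non-goals.
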
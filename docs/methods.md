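# Methods

This note documents the statistical machinery implemented in
`mc_activity`, the synthetic-data model used to exercise it, and the design
choices made where more than one reasonable construction existed.

## Instruments and scoring

The MCSQ diary records, per day over one week: total stools, nocturnal
stools (those disrupting sleep, counted as a subset of the same calendar
day's total), Bristol-6 (mushy) and Bristol-7 (watery) stools, solid
stools, urgency and fecal leakage occurrence, and a 0–3 abdominal-pain
rating. Daily urgency/leakage are binary occurrences aggregated to
days/week; pain is averaged. These response formats for urgency, leakage
and pain are declared package conventions — ordinal-per-day variants can be
accommodated at the aggregation layer. Weekly summaries average over
recorded days; diaries with ≥ 4 of 7 days are accepted as partial (mean
items are robust to missing days) and the day-count items are rescaled to a
7-day week. Loose stools are defined as Bristol 6 + Bristol 7; total
stools are reported independently but must dominate both loose and solid
means.

Hjortswang activity uses exact `>=` comparisons on unrounded weekly means
(mean total ≥ 3/day or mean Bristol-7 ≥ 1/day). IBDQ-32 scoring sums the
1–7 item responses (total 32–224) and the standard 10/5/5/12 domain
partition (bowel/systemic/social/emotional); the item→domain map is an
argument so licensed orderings can be swapped in. The Short Health Scale's
four 1–6 dimensions are reported separately, never summed.

The MCS sums item-specific points over five items — mean loose stools,
mean nocturnal stools, urgency days, leakage days, mean pain — with 0–3
points each (maximum 15). Mean solid stools and mean total stools are
structurally excluded: solid stools carry no diarrhea information and the
total is derivable (and less predictive of HRQoL) — the table classes
refuse to hold them. Intervals are half-open, `[t_i, t_{i+1})`, with the
top interval closed above by +∞, matching the ≥-style thresholds used for
the activity rule. Severity classes partition the integer score:
remission 0–3, mild 4–6, moderate 7–9, severe 10–15.

The **default score table** shipped in `data/mcs_table.cfg` was produced by
running the calibration below on a pinned synthetic reference cohort
(generator seed 20259, n = 500, baseline, no missingness). It is a
placeholder with the correct structure, not a clinically validated table;
replace it with a published table via `load_score_table`.

## Calibration (cut-off derivation)

Cut-offs are anchored to the IBDQ-32: one awarded point should correspond
to a 15–20-point decrease in IBDQ total (one clinically significant
difference). Two anchoring styles exist: matching raw category-mean gaps,
or anchoring on the regression prediction. We use **regression-prediction
anchoring**: the univariate OLS slope `b` (IBDQ points per item unit) sets
a uniform category width `w = 17.5/|b|`, so each point corresponds to a
predicted 17.5-point drop — the middle of the window, and inside it for any
width in `[15/|b|, 20/|b|]`. The threshold offset is chosen on a fine grid
(80 steps over one width) to maximize the between-category variance of
IBDQ, which aligns boundaries with natural gaps in the item's value
distribution; plateaus of equally good offsets resolve to their middle, so
clumped data get mid-gap boundaries. Categories must hold ≥ 5
observations (stabilizes means at the ~130-patient scale); the threshold
count starts at the 3-point budget and is reduced only when occupancy
fails. Items with a non-negative or non-significant (F-test p > 0.05)
IBDQ association are flagged and carry 0 points.

The category-mean alternative was implemented first and rejected on
measurement grounds: with IBDQ residual SD ≈ 15–20 and ~30 observations
per category, the standard error of an adjacent-category mean gap (~3.7
points) exceeds the half-width of the 15–20 window, so the generating
partition is usually "infeasible" and the search latches onto noise
(0/50 simulated runs recovered planted boundaries). Regression anchoring
recovers planted unit boundaries within a quarter of the level spacing in
96% of runs at n = 500.

The diarrhea-item selection fits all univariate models for mean loose,
Bristol-6 and Bristol-7 counts plus every two-variable combination (the
triple is exactly collinear, since loose = B6 + B7, and is excluded),
picks the best univariate item by adjusted R², and reports whether any
multivariate model adds more than ε = 0.01 adjusted R² ("meaningful"
improvement threshold, configurable).

Table assembly drops entries for the excluded items with a warning,
rescales point ceilings by largest-remainder apportionment when the maxima
do not sum to 15 (merging top categories or splitting the widest gap as
needed, warned), and errors when 15 is unreachable under the per-item cap.

## Psychometric battery

* **Bartlett's sphericity**: χ² = −(n−1−(2p+5)/6)·ln det R, df = p(p−1)/2.
* **KMO**: Σr² / (Σr² + Σq²) over off-diagonal entries, with anti-image
  partials q from the inverse correlation matrix; per-item MSA analogous.
* **Parallel analysis**: observed correlation eigenvalues against the 95th
  percentile of eigenvalues from column-permuted data (preserves
  marginals), 500 replicates by default; the suggested factor count is the
  leading run of exceedances.
* **EFA**: minimum-residual extraction — bounded L-BFGS-B over the
  uniquenesses (start at 1 − squared multiple correlation, bounds
  [0.005, 1]), loadings from the top-m eigenpairs of the reduced matrix;
  Heywood communalities are clamped with a flag. Rotation: Kaiser-
  normalized varimax followed by the classical promax power-4 oblique
  target regression; factors are ordered by explained sum of squares with
  non-negative loading sums, making output deterministic. The test suite
  cross-checks extraction against statsmodels' principal-axis factoring on
  exact-structure matrices and the rotation against values frozen from
  R's `stats::promax`.
* **Cronbach's α**: k/(k−1)·(1 − Σ item variances / total variance).
  Because loose = B6 + B7 and total = loose + solid *exactly*, the
  correlation-based analyses (Bartlett, KMO, EFA, α) run on the seven
  non-derived items; including exact sums would make R singular.
* **ICC(2,k)**: two-way random effects, absolute agreement, average
  measures — (MSR − MSE)/(MSR + (MSC − MSE)/n) — with listwise deletion
  and the F-distribution CI (single-measure bounds with Satterthwaite
  degrees of freedom, stepped up by Spearman–Brown). Cross-checked against
  pingouin's ICC(A,k) to 1e−10.
* **Responsiveness**: paired Wilcoxon signed-rank per item between
  baseline and follow-up of the treated arm; the exact null for ≤ 25
  untied informative pairs, tie-corrected normal approximation otherwise;
  Bonferroni over the number of items. All-zero differences yield p = 1
  with a flag.
* **Convergent validity**: per-hypothesis Pearson (interval pairs) or
  Spearman (ordinal pairs), met when |r| ≥ 0.4 with the expected sign and
  Bonferroni-adjusted p < 0.05. The Pearson/Spearman assignment is an
  explicit per-pair policy because the appropriate coefficient differs by
  measurement level.

## Severity clustering

Rows (patient-timepoints) with > 20% missing features are removed first,
then columns with > 20% missingness among the remaining rows — the row
filter protects patients' columns from being dropped for missingness that
is concentrated in a few bad records. Imputation is missForest-style:
initialize at column means, regress each incomplete column on all others
with a random forest (columns in ascending missingness order), iterate
until the normalized change increases (keeping the previous round) or 10
iterations. Observed cells are never altered, and forest predictions are
averages of observed values, hence within the observed column range.

Features are one-hot encoded and z-scored, then reduced by PCA. JackStraw
assigns significance to components: each replicate scrambles ~1% of the
columns (at least one), recomputes the PCA, and pools the squared
feature–component correlations of the scrambled columns as the null; each
real feature gets an empirical p per component, and a component is
significant when more features beat α = 0.05 than a binomial null allows.
The embedding keeps `max(significant count, 8)` dimensions. The floor
matters: on one-factor-dominated tables the permutation test certifies only
1–2 components, and in such low-dimensional embeddings the k-nearest-
neighbor graph of a homogeneous patient group is chain-like, which the
Leiden objective fragments (simulated isotropic 45-point groups split
10/10 at 1–2 dimensions, 0/10 at 8). Padding with noise-dominated
components mixes within-group neighborhoods without diluting between-group
separation.

The SNN graph takes each point's k = 10 nearest Euclidean neighbors
(including itself; distance ties break by index, so duplicated points get
identical neighborhoods), weights every pair by the Jaccard overlap of
their neighborhoods, and prunes weights below 1/15. Leiden optimizes
resolution-parameterized modularity (configuration null, γ = 0.9, 10
iterations, seeded). Clusters are annotated on the five-level severity
vocabulary ordered by burden (mean loose stools ascending, IBDQ total
descending, size as tie-break, logged); fewer clusters take labels from
the extremes inward, more than five get roman-numeral suffixes so the
annotation stays a bijection.

The default clustering feature set is the nine diary summaries, four IBDQ
domain scores, four SHS dimensions, and the patient's 0–3 symptom rating.
Age, sex and disease duration are excluded by default: they carry no
severity signal, and pure-nuisance dimensions measurably degrade recovery
of the severity structure; pass `features=` to include them.

## ROC analysis

Curves sweep the unique score values (tie-aware); the trapezoid AUC equals
the Mann–Whitney concordance probability, which the suite asserts to
1e−12. The operating point maximizes Youden's J (ties toward the lower
cut-off, favoring sensitivity); a closest-to-(0,1) criterion is available.
Integer cut-offs are reported in the "MCS ≥ c" convention. Four contrasts
are evaluated: Hjortswang activity, and any-active / moderate-or-severe /
severe by cluster annotation; one-class contrasts are skipped with a
warning.

## Synthetic cohort model

Real cohorts of this design are not publicly shareable, so the generator
produces what the analyses assume, with ground truth retained:

* **Strata as symptom profiles.** Five severity strata with weights
  0.31/0.25/0.15/0.15/0.14 (remission → severe; the three active strata
  plus the partially active borderline reproduce a ~49% baseline activity
  fraction, i.e. a 1:1 remission:active recruitment design). Each stratum has a
  typical item-category vector — e.g. remission (0,0,0,0,0), severe
  (3,3,3,2,3) — and each item flips one step with probability 0.04 per
  patient-occasion. True MCS = category sum; the strata are distinct
  profiles rather than slices of a featureless continuum, which is what
  "clusterable severity groups" means.
* **Diaries.** Daily counts are negative-binomial (dispersion 10) around a
  weekly intensity drawn from category-specific bands (e.g. loose stools:
  0–0.5, 1.5–2.3, 3.6–4.8, 6.5–8.5 per day for categories 0–3); the
  Bristol-7 share of loose stools rises with stratum (0.15 → 0.85), so
  moderate/severe diarrhea is watery-dominated while mild disease is
  mostly Bristol 6. Urgency/leakage are Bernoulli days, pain a discretized
  Gaussian around category levels. Band and probability values were set by
  simulation so the declared stratum-level targets hold (≥ 95% of
  remission-stratum patients classify as Hjortswang remission, severe
  expected MCS ≥ 10, expected MCS strictly increasing across strata).
* **HRQoL anchor.** IBDQ total = 202.3 − 6.0·MCS + N(0, 20²), clamped to
  [32, 224]; with the strata above this reproduces an adjusted R² ≈ 0.6
  for the univariate regression. Item responses realize the target total
  exactly by largest-remainder allocation across domains (shares jittered
  12% so domains are not perfectly collinear) and even spread within
  domains. SHS dimensions and the 0–3 patient rating are clipped, rounded
  monotone maps of true MCS with Gaussian noise (SD 0.4–0.55).
* **Follow-up.** Patients in an active stratum are "treated" (flagged in
  the cohort table) and move down two strata at follow-up; untreated
  patients redraw only the flip noise, giving test–retest stability. A
  dedicated `generate_retest_data` produces subject×occasion scores with an
  exact population ICC(2,k) via the closed-form variance ratio
  σ²ₑ = k·σ²_b·(1−ρ)/ρ, used for reliability benchmarking (target 0.88).
* **Missingness.** MCAR holes at rate 0.03 (the residual missingness scale
  of such studies) over the feature columns, with the mask returned;
  identifiers, the activity label, and the treatment flag are never masked.

What the generator does **not** emulate: recall bias of retrospective
diaries, country/subtype heterogeneity, informative (non-MCAR)
missingness, IBS-specific symptom inflation (IBS is an independent flag),
and floor/ceiling idiosyncrasies of real Likert data beyond clipping.
Passing recovery tests therefore demonstrates the pipeline's correctness
under its stated assumptions, not clinical validity on real cohorts.

Ceiling clamping at IBDQ 224 mildly attenuates the recovered slope
(≈ −5.6 to −5.8 instead of −6.0 at n = 500); the recovery band (±0.8)
accounts for this known, realistic censoring effect.

## Problem sizes and determinism

The test suite runs the heavy recoveries at reduced but statistically
meaningful sizes chosen as the package's own benchmarks: slope/ICC recovery
over 100 seeds (n = 500 cohorts, n = 60 retest), calibration recovery over
50 seeds at n = 500, clustering recovery over 20 seeds on baseline records
(n = 131; the five planted strata exist at baseline — follow-up rows are
treatment-shifted mixtures whose pooled remission mass exceeds what the
fixed k = 10 / γ = 0.9 granularity can hold together, which is also why
studies of this design report remission splitting into several clusters).
Random-forest imputation uses 30–50 trees and JackStraw 120–200
permutations in the suites (1000 in production defaults).

All randomness flows through `numpy.random.default_rng` seeds; the
pipeline derives per-stage seeds from a master seed by SHA-256, records
them in the run manifest, and identical configurations hash to identical
manifests, so every numeric output is bit-reproducible.

## Known limitations

* The packaged score table is calibrated on synthetic data; clinical use
  requires the published item table.
* EFA uses Pearson correlations; polychoric correlations for ordinal items
  are out of scope.
* No confirmatory factor analysis / SEM fit indices, no IRT models, and no
  DeLong CIs for AUC.
* The imputer treats one-hot/categorical codes as numeric regressands;
  with only binary categoricals in the default feature sets this is
  harmless, but many-level categoricals would deserve a classification
  forest.
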
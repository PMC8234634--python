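# Methods

## Reference structure (the stand-in for real feature summaries)

Real radiomic feature tables are proprietary, so the simulator consumes
a *reference structure*: per-feature target moments and ranges plus a
feature–feature correlation matrix, per reconstruction stratum (FBP and
IR). `build_reference_stats` generates a parametric stand-in; real
summaries can be supplied through `load_reference_stats` (CSV moments +
CSV correlation matrix).

The stand-in mimics the qualitative description of real NSCLC CT
radiomics: features fall into correlated families, are mostly
non-normal, and span very different physical ranges.

| parameter | default | meaning |
|---|---|---|
| `n_features` | 168 | features per stratum |
| `n_blocks` | 8 | correlated feature families |
| `within` / `between` | 0.7 / 0.1 | block correlation template |
| `normal_fraction` | 0.32 | fraction of approximately normal features |
| `skew_range` | (0.5, 3.0) | skewness γ₁ of non-normal features (uniform) |
| `kurt_margin` | (0.3, 6.0) | excess kurtosis γ₂, uniform above the Fleishman feasibility boundary |
| ranges | [0, 100·10^k] | per-block magnitudes cycling over decades (k = −1 … 3) |

Non-normal (γ₁, γ₂) draws are rejected (and redrawn) unless the
Fleishman system admits a solution. The three control features that
will carry the outcome signal sit in three well-separated blocks, so
their mutual correlation is low and the planted signal is not
redundant.

## Non-normal simulation

The Fleishman solver runs damped Newton/hybrid iterations from a fixed
multi-start grid (including the normal solution (b,c,d) = (1,0,0)) and
accepts a root when the moment residual is below 1e−8; among
sign-symmetric solutions it returns the one with b > 0, preferring the
branch continuous with the normal case. Negative skewness re-uses the
positive-skew solution with c negated.

The Vale–Maurelli cubic is solved per feature pair by polynomial
root-finding (tolerance 1e−10), taking the real root in [−1, 1] nearest
the target. Because the pairwise intermediate matrix need not be
positive semidefinite, it is repaired by projection to the nearest
correlation matrix (alternating projections with a bounded iteration
budget, then an eigenvalue clip-and-renormalize polish to guarantee a
minimum eigenvalue of 1e−8). The repair can only move correlations
*toward* feasibility, which — together with attenuation from the
polynomial transform — means achieved correlations sit at or slightly
below the targets, never systematically above. At n = 10⁵ the mean
absolute deviation between achieved and target correlations is ≈ 0.003.

One caveat on moment checks: the sampling error of excess kurtosis
grows quickly with the tail weight, so recovery at ±0.2 tolerance is
asserted for moderate (γ₁, γ₂) only; very heavy tails (γ₂ ≳ 15) need
more than 10⁶ draws for that precision.

## Scenario construction

Class totals (50% or 30% positives), stratum totals (FBP:IR = 2:1), and
the per-(stratum × class) table are all apportioned by the
largest-remainder method; strata are filled in order with the last
stratum absorbing remainders, so both margins hold exactly at every
size (600, 300, 100). The 2/3–1/3 training/validation split is
stratified by (class × stratum) with the same apportionment. Smaller
cohorts are drawn *nested* inside larger ones by default, separately
within each (stratum × class × split) cell, so training/validation
membership is preserved down the size ladder; an independent-draw mode
is available (`nested=False`).

The outcome signal is injected after range rescaling: each control
feature is shifted additively in the positive class by δ times its
pre-shift cohort standard deviation (equal to the pooled within-class
SD). δ_high = (2, 2, 2) makes all three controls strongly significant;
δ_low = (1.2, 0.8, 0.5) makes only the larger shifts reliably
detectable at small n. Real clinical effect sizes vary from cohort to
cohort; these values are this package's calibration, chosen once so
that the high-signal scenario is nearly saturating for tree models on
large samples while the low-signal scenario is not, and they are
exposed in `ScenarioSpec.shifts`.

Negative-class rows are bit-for-bit untouched by injection.

## Feature selection

All methods fit on training data only; ties always break by feature
order.

* **WLCX** — two-sided Wilcoxon rank-sum per feature (exact null for
  small untied samples, tie-corrected normal approximation otherwise);
  keep p < α (default 0.05), falling back to the 5 smallest p-values if
  none pass, so downstream models never receive an empty table.
* **HC+WLCX** — average-linkage clustering on 1 − |Spearman ρ|, cut at
  height 1 − 0.75; cluster representative = medoid (largest mean
  absolute correlation to the other members); WLCX on representatives.
* **PCA+WLCX** — PCA on standardized features; K retained components by
  either the *proportion* criterion (smallest K with cumulative
  explained variance ≥ 0.80) or the *delta-plot* criterion. The delta
  plot is read as: retain components up to the **last** appreciable
  drop of the sorted eigenvalues (a gap exceeding five times the median
  gap), falling back to the single largest gap. A naive
  "largest-single-gap" elbow collapses to K ≤ 2 whenever a dominant
  global factor is present — as it is here by construction — which
  would hide all later structure, including the components carrying the
  planted controls. Features are grouped by their maximal absolute
  loading among the K components; the representative of each group is
  the feature with the largest absolute loading; WLCX on
  representatives. Original features (never component scores) are
  passed downstream so importance rankings stay in feature space.
* **MRMR** — greedy forward selection of m = 20 features maximizing
  I(f; y) − mean I(f; s) over the selected set (MID scheme), with
  mutual information estimated on equal-frequency 3-bin
  discretizations (robust to the skewed marginals this simulator
  produces).
* **RELF (ReliefF)** — all training instances, k = 10 nearest hits and
  misses, Manhattan distance on [0, 1]-scaled features; top m = 20 by
  weight.

## Classifiers

PR, KNN, SVM and LSR are standardized with training-fold statistics
inside their pipelines. Hyperparameters maximize stratified 5-fold
cross-validated AUC (3-fold and lighter grids in the "fast" profile
used for large sweeps):

* PR: elastic-net logistic regression, C ∈ {0.1, 1}, l1_ratio ∈ {0, 0.5, 1};
* RF: 300 trees, max_features ∈ {√p, p/3, p/10};
* XGBoost: 200 rounds (hist), depth ∈ {2, 4, 6}, learning rate ∈ {0.05, 0.3};
* KNN: k ∈ {3, 5, …, 21};
* SVM: RBF with the median-heuristic width ± one factor-of-4 step and
  C ∈ {0.25, 1, 4}. Scores are the logistic map of the decision values —
  a strictly monotone transform, so AUC equals the margin AUC and the
  decision boundary maps to probability 0.5;
* LSR: bidirectional stepwise logistic regression by AIC. It refuses
  more than 50 candidate features (stepwise selection with p close to n
  is unstable), which excludes the no-FS setting for this model.

SMOTE (k = 5 minority neighbours, uniform interpolation) is applied to
training folds only, and only in unbalanced scenarios, up to exact
class parity. Sensitivity/specificity use a fixed probability threshold
of 0.5 — the simplest reproducible rule, meaningful because unbalanced
training sets are SMOTE-balanced; it is exposed in `BenchmarkConfig`.

## Orchestration and randomness

`run_benchmark` sweeps scenario × FS × classifier × replicate. One
master seed drives everything; each stage derives a child seed by
hashing the stage labels with the master seed, so results are
reproducible and independent of execution order. Failed cells are
recorded with their reason, excluded from aggregates, and counted in
the run manifest — never silently skipped. LSR under no-FS is skipped
by design, giving 12 × (6 × 6 − 1) = 420 cells per replicate on the
full grid.

## Problem sizes used by the shipped checks

The test suite exercises the qualitative findings (tree models dominate
KNN/SVM; small samples vary more; no-FS is best for
selection-embedded classifiers and worst for distance-based ones; SMOTE
does not hurt sensitivity; high-signal controls are recovered in the
top-20) on a reduced configuration — sizes 300 and 100, one replicate,
fast tuning grids — and the absolute AUC levels of RF/XGBoost on the
large (600) scenarios over five seeded replicates with the default
grids. The acceptance script uses the full default grids and five
replicates for its two headline numbers.

## What the generator does and does not emulate

It reproduces: block-correlated, mostly non-normal marginals with
realistic range heterogeneity; exact design counts; a sparse planted
signal. It does **not** reproduce: the full-rank "messiness" of real
radiomic correlation spectra (the block template is low-rank, which
makes distance-based classifiers look better without FS than they do on
real data), scanner/acquisition batch effects, feature
non-stationarity, or label noise. Absolute AUC levels therefore
transfer to real data only loosely; the *comparative* conclusions
(which methods degrade under small n, imbalance, weak signal) are the
meaningful output. Because training and validation samples come from
the same simulated population, validation performance is optimistic
relative to external validation — uniformly across methods, so
comparisons stand.

## Known limitations

* Per-feature moments and separation factors of real clinical cohorts
  are rarely available; all defaults here are this package's own
  calibration.
* Kurtosis recovery checks are limited by estimator variance for very
  heavy tails (see above).
* `fleishman_feasible` is solver-based: a pair is declared infeasible
  when no start point converges, which is conservative near the
  theoretical boundary.
* Stepwise logistic regression can legitimately retain zero terms on
  weak-signal folds; such cells report zero recovered controls.
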
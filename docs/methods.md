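# Methods

## Problem setting and model

`robustcheck` targets tabular, continuous, multivariate biomarker data:
an N×F matrix of non-negative measurements (metabolite concentrations in
the motivating use case) with a binary diagnosis label per sample. The
question it answers is not "which classifier is best?" but "is this
already-built classifier robust?" — operationalized as (a) whether the
classifier's input features are among the statistically meaningful features
of the dataset, and (b) how much the classifier's accuracy and parameter
values move under feature-level perturbations and split resampling. Mean
behavior is estimated by Monte Carlo averaging; sensitivity by the Monte
Carlo variance.

## Feature-significance screen

**Leave-out FDR.** The per-feature "false discovery rate" here is a
stability score, not the Benjamini–Hochberg procedure: the fraction of
leave-one-out and leave-two-out subsamples on which the two-group test
fails to reach p ≤ 0.05. A feature that is significant on the full data but
loses significance when one or two samples are dropped is fragile; the
filter removes features with FDR > 0.1 (boundary value kept). The FDR is an
exact ratio of integer counts. Depth-2 enumeration costs N(N−1)/2 tests per
feature; `max_pairs` (seeded subsampling of pairs) bounds this for larger
tables, and the test suite uses `max_pairs=300` on the 159-sample fixture
to keep runtimes in seconds without changing any qualitative outcome.

**Test triage.** Which two-group test applies is decided per subsample:
Shapiro–Wilk normality on both groups at α = 0.05; if neither rejects,
Levene's test chooses between the equal-variance and Welch t-tests;
otherwise the Mann–Whitney U test. Two refinements cover degenerate
subsamples: a zero-variance group is routed to the rank-based branch
(Shapiro–Wilk is undefined on constants), and a group with fewer than three
values — too few for Shapiro–Wilk — is treated as "normality not rejected"
and may take the parametric branch. The latter matters: the exact
Mann–Whitney two-sided p-value for perfectly separated groups of sizes 2
and 4 is 2/15 ≈ 0.13, so a rank-only fallback would call perfectly
separated tiny groups non-significant.

**Component retention and loadings.** Horn's parallel analysis retains
components from the top while the observed eigenvalue exceeds the matching
rank's 95th percentile over 1000 same-shape standard-normal matrices
(defaults configurable). Retaining zero components is an error — the data
show no structure beyond noise. Loadings default to `A = P·V^(−1/2)`;
the conventional alternative `V^(+1/2)` is available via
`exponent_convention=+0.5` and recorded in the output. Because `V^(±1/2)`
is a positive diagonal, the two conventions share their sign pattern and
the downstream k-means grouping is nearly always identical; the default
follows the shrunken form for continuity with the screen's provenance.

**Cluster pruning.** k-means (10 seeded restarts, k ∈ 2..min(10, m−1))
on the loading rows; k maximizes the mean per-cluster silhouette
`s_c = (b_c − a_c)/max(a_c, b_c)` with `a_c` the mean within-cluster
pairwise distance and `b_c` the mean distance to the nearest other
cluster. This per-cluster statistic is computed in-package; library
silhouettes are per-sample and average differently. "Sufficiently tight" is
s_c ≥ 0.5 (configurable); a tight cluster keeps its 3 members closest to
the centroid (ties broken by lowest feature index). Fewer than 3 surviving
features skip clustering entirely.

**Logistic variance screen.** The probe variance of feature f is
analytically `w_f²` (variance of `w_f·Z`); it is estimated by Monte Carlo
(default 100 000 draws) to keep the published procedure's form, and the
retention rule "scaled variance ≥ 2 of max 8" is therefore equivalent to
`|w_f| ≥ 0.5·max|w|` up to Monte Carlo error. The cap of 8 corresponds to
√8 ≈ 2.83 standard deviations; the package reports the one-sided normal
coverage Φ(√8) ≈ 99.77% for this rationale (the two-sided coverage would
be 99.53%).

## Noise models

Both engines operate on the raw scale, before any standardization, because
measurement error lives on the raw scale. Column statistics (mean, ddof-1
SD) always come from the clean column. Replacement noise rounds
`v = p·N` half-to-even, chooses v row positions per column uniformly
without replacement, and overwrites them with `N(μ_f, σ_f²)` draws;
a constant column is "replaced" by its own mean. Gaussian noise adds
`N(0, (s·σ_f)²)` elementwise; negatives are clipped to zero by default
(concentration data), while replacement clipping defaults off to keep the
replacement distribution exactly the fitted normal. Each (seed, column)
pair draws from an independent `SeedSequence`-spawned stream, so results do
not depend on column evaluation order.

## Monte Carlo protocols

**Severity sweep.** Levels default to 0, 0.1, …, 1.0; each level is
corrupted `reps_per_level` times (published scale: 1000; the CLI `--fast`
preset and most tests use 100, which recovers every trend at proportionally
wider Monte Carlo error). The split is fixed across all reps and levels so
that only the noise varies. Within a rep, standardization is fitted on the
corrupted training partition and applied to the corrupted test partition —
leakage-safe while still corrupting before standardization. Level 0 is an
identity corruption and is evaluated once with variance 0 by construction.
Rep r at level index ℓ derives its seed from `SeedSequence([master, ℓ, r])`,
making partial and parallel runs reproduce the serial result. LOOCV inside
the sweep corrupts once per rep and cross-validates the corrupted training
partition (it does not re-corrupt per fold).

**Split study.** Stratified 70/30 splits by default: with ~159 samples a
non-stratified 30% partition can lose a class entirely, and stratification
keeps the near-balance that makes the 50% replacement asymptote meaningful.
Variance uses ddof = 1 throughout.

**Tolerable noise.** Under replacement noise, mean accuracy decays
approximately linearly from acc(0) to 0.5 at p = 1, so the level at which
accuracy crosses a clinical target (e.g. 80%) is
`p* = (acc(0) − target)/(acc(0) − 0.5)`; the empirical grid crossing is
interpolated alongside as a sanity check.

## Classifier adapters

All six adapters consume standardized matrices and expose
fit/predict/extract-parameters. Where the published account is silent on
hyperparameters, scikit-learn ecosystem defaults are used and everything is
overridable: LDA (svd solver), SVM linear kernel C = 1 (linear so that
per-feature coefficients exist for parameter tracking), random forest with
16 Gini trees, PLS-DA with one component and a 0.5 threshold on the
continuous output (ties to class 1), logistic regression with L2/SAGA
(max 5000 iterations), MLP 32→16 ReLU with Adam (max 1000 iterations,
seeded). Parameters are signed coefficients for the linear models,
normalized mean-Gini-decrease importances for the forest, and none for the
MLP — conclusions about parameter stability are limited for models without
per-feature weights. No sign alignment is applied across reps; with fixed
label coding the linear-model signs are stable.

Wrapper selection enumerates k-subsets in name-sorted order (ties therefore
break lexicographically, independent of column order) and scores each by
LOOCV accuracy on the training partition of a fixed split. Prevalence
ranking repeats selection over many random splits, scoring subsets by
test-partition accuracy, and prefers the most frequent winning subset whose
members all sit in the top third of per-feature prevalence.

## Synthetic data generator

The generator emulates the shape and statistical structure of a small
two-class clinical metabolomics study: 83 cases / 76 controls, 24 features,
5 informative. Informative features form an equicorrelated Gaussian block
(ρ = 0.5 by default, built from a shared latent factor) with a class-mean
shift of `effect_size` marginal SDs; null features are independent
standard normals. Non-negative support is imposed by shifting each feature
by 3.1 SD plus the class shift (< 0.1% of mass below zero) and clipping at
zero, which keeps the clip-negative noise path exercised. Rows are
shuffled so row order carries no label signal.

The reference fixture pins `effect_size = 2.47`, obtained by bisection
(`calibrate_separation`) against a 94% mean LDA test-accuracy target over
stratified 70/30 splits; bisection works because accuracy is monotone in
the effect size up to Monte Carlo jitter on a fixed split batch.

What the generator does **not** emulate: batch effects and drift,
limits of detection, heavy-tailed or skewed concentration marginals,
pathway stoichiometry, and correlated null features. Passing tests on this
fixture therefore demonstrate the machinery's correctness and its
qualitative behavior (chance asymptote, linear decay, variance orderings),
not performance guarantees on any real cohort.

## Numerical choices and degenerate inputs

- Standardization uses ddof-1 SDs and rejects constant features explicitly.
- Labels are coerced to {0,1} by mapping the lexicographically smaller
  value to 0; the coding is recorded in table metadata.
- CSV I/O uses round-trip float parsing; read→write→read is lossless to
  1e-12.
- A leave-out subsample that would drop a class below 2 members is skipped
  and the FDR denominator decremented.
- Split-study and sweep failures (degenerate reps) are logged and excluded;
  more than 5% failures at a level aborts the sweep.

## Known limitations

LOOCV on label-free (null) data is pessimistically biased — holding out a
sample tilts the empirical class priors toward the opposite class — so
null-data sanity checks are stated on test-partition accuracy, which is
unbiased. The MLP contributes accuracy trajectories only. The noise models
are calibrated to tabular measurement error; imaging-style noise is out of
scope.
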
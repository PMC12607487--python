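# Methods

## Scope and data model

The package operates on tables of GC/MS *relative abundances*: each
sample's identified peak areas expressed as percent of total, so values
are non-negative and per-sample sums are at most 100 (they may fall short,
because unidentified peaks are excluded; validation allows a 0.5-point
tolerance for printed-precision round-off). Missing cells in input CSVs
(`""`, `-`) are read as 0 — in this data type an absent entry means the
compound was not detected in that extract, not that the measurement is
unknown. Class labels are binary; the display-name → {0, 1} coding is
assigned lexicographically and recorded in the output, so sign conventions
in downstream models are reproducible. All statistics are invariant to
which class is coded 1.

## Preprocessing

**Cutoff filter.** A feature is "major" if its relative abundance reaches
the threshold (default 10%, inclusive) in at least one sample
(`rule="any_sample"`); `all_samples` and `mean` variants are provided for
sensitivity analysis. The any-sample reading is the weakest rule that
still yields a per-group list of major components, and it makes the filter
idempotent and monotone in the threshold.

**Standardization.** Two conventions, both with the n−1 standard
deviation so that z-scores, Pearson correlations and PCA variance
bookkeeping agree: per-feature z-scoring of the features × samples table
(the clustered-heatmap input), and column autoscaling of the samples ×
features matrix (PCA/PLS-DA input). Zero-variance features are an error,
never silently zeroed. In cross-validation the autoscaler always applies
training-fold statistics to held-out samples; the `fit_stats` argument
exists precisely so that leakage is structurally impossible.

## Hierarchical clustering

Agglomerative clustering (scipy linkage; default average linkage on
Euclidean distances, the defaults of the common clustered-heatmap tools)
on both samples and features of the z-scored table. Results are emitted as
data artifacts — merge tables (node_a, node_b, height, size) and leaf
orders — rather than rendered dendrograms; tie-breaking among equal merge
heights follows scipy's deterministic order. Merge heights are
cross-checked in the tests against a brute-force O(n³) agglomeration.

## PCA

SVD of the centered (by default also autoscaled) matrix;
explained-variance ratio of component i is s²ᵢ/Σⱼs²ⱼ. Requested components
are capped at min(n−1, p). Each component's sign is fixed so its
largest-magnitude loading entry is positive, making scores reproducible
across BLAS implementations.

## Correlation-based feature selection

The Pearson matrix (n−1 convention, diagonal exactly 1) is thresholded on
|r| (default 0.7) and its connected components form correlation clusters,
ordered by smallest member index. One representative per cluster is chosen
by maximum mean abundance (or maximum VIP when a fitted model supplies
one), clusters are ranked by their representative's criterion value, and
the top `n_select` (default 4) are kept; all ties break alphabetically.
Connected components are the simplest reproducible reading of
"correlation clusters"; both the threshold and the number of
representatives are exposed because neither is canonical — on a given
dataset the threshold can be scanned until the cluster count matches a
target (the shipped preset yields six clusters at 0.7).

## PLS-DA

Single-response NIPALS (PLS1) on the autoscaled X against the 0/1 class
coding, deflating X only; weights are unit-norm, scores mutually
orthogonal, coefficients b = W(P'W)⁻¹q. Two latent variables by default —
enough for a score plot and appropriate for n = 12. The decision threshold
on ŷ is 0.5.

- **R²** is computed on training data from SSE = Σ(yᵢ−ŷᵢ)² and
  SST = Σ(yᵢ−ȳ)²; the stored object keeps both sums so the identity
  R² = 1 − SSE/SST is exact by construction.
- **Q²** uses stratified k-fold CV (default k = 5, shuffled under a
  recorded seed). Stratification matters: with 12 samples and 5 folds an
  unstratified split can produce a single-class training fold, which is an
  error, not a warning. PRESS accumulates held-out squared errors; TSS
  accumulates held-out squared deviations from the *training-fold* mean,
  so Q² = 0 corresponds exactly to the training-mean predictor. A
  `tss_mean="global"` switch provides the global-mean variant.
- **Permutation test**: each of n_runs (default 1000) shuffles y uniformly
  at random, keeps X fixed, and recomputes the full CV with fresh
  stratified folds; p = #(Q²_perm ≥ Q²_obs)/n_runs, the literal counting
  estimator (p = 0 is attainable; the (count+1)/(n+1) convention is
  available behind `plus_one=True`).
- **VIP** uses the standard Wold formula weighting squared weights by each
  component's explained response variance SSYₐ = q²ₐ·t_a't_a. The mean of
  squared VIPs is 1 for every fitted model (checked to 1e-9), so VIP > 1
  is a scale-free importance flag.

The NIPALS fit is cross-checked in the tests against two independent
routes: a Krylov-subspace least-squares oracle (PLS1 coefficients equal
the LS solution restricted to span{X'y, (X'X)X'y, …}) and sklearn's
`PLSRegression` predictions.

## Synergy statistics

Percent inhibition is (A_control − A_sample)/A_control × 100; negative
values (activation) are legitimate. Combination improvement is
(combined − single)/single × 100 against *each* single agent of the pair.
For docking energies the ratio uses score magnitudes: binding scores are
negative by convention, "improvement" means an increase in magnitude, and
a sign-literal ratio is meaningless when a printed score has the opposite
sign. Reported values are rounded half-away-from-zero to integers; raw
values are retained. Improvements are keyed by (pair, reference agent),
never by bracket position.

## Synthetic-data generator

The generator emulates a two-class profiling design: 12 samples = 2
classes × (2 cultivars × 3 extract types), 61 features of which exactly 13
are major and 3 discriminative. Per sample, log-normal raw intensities
(σ = 0.35; majors on a 12× baseline over minors) are closed to
percent-of-total. Three mechanisms shape the data:

- **Class effect**: each discriminative feature's log-mean is shifted
  ±effect_size·σ/2 by class (default effect_size 4, i.e. a 4-pooled-sd
  separation on the latent log scale; closure attenuates the realized
  separation in percent units). Elevated classes alternate, mirroring a
  linoleic-acid-high group versus a clionasterol-high group.
- **Extract structure**: every non-discriminative major is boosted 6× in
  one of the three extract types, in both classes — extract-specific
  dominant peaks are the main *non-class* variance, as in real multi-
  extract designs, and the symmetry keeps the null exactly null.
- **Determinism of the major/minor split**: after closure, minors are
  capped at 9% everywhere and any major whose maximum falls below 10% is
  floored at 10.5% at its maximum sample (renormalizing the rest of that
  sample, iterating until stable). The cutoff stage therefore has a known
  61 → 13 ground truth at every seed.

What the generator does *not* emulate: retention-time/peak-shape effects,
within-cultivar biological replication structure, heteroscedastic
detector noise, or realistic correlation between specific metabolite
pairs. Passing tests demonstrate the pipeline's statistical behaviour
under a compositional, extract-structured two-class design — not
instrument-level realism.

A note on permutation calibration: with the balanced design labeling,
label permutations are *not* exchangeable with the observed labels once X
contains extract structure — a shuffled labeling that happens to align
with extract type is genuinely easier to predict, so p-values under
"effect = 0 plus design labels" are conservative. The calibration tests
therefore draw the observed labeling at random (`generate_null_labels`),
which restores exchangeability and yields uniform p-values. Practitioners
should expect the same conservatism when permuting labels on real data
with strong batch-like structure.

The bioactivity fixture plants three singles near 40% inhibition and
pairwise combinations with known integer improvements (25–115%), chosen
so that two-decimal CSV round-tripping still recovers the planted integers
exactly.

## Numerical and design choices

- NIPALS stops with an error if X retains no covariance with y at a
  requested component (degenerate deflation) rather than returning junk
  components.
- Component caps: PLS and PCA both require n_components ≤ min(n−1, p).
- All stochastic steps (fold shuffles, permutations, the generator) take
  explicit seeds; pipeline runs derive per-stage seeds from one master
  seed with `numpy.random.default_rng` and record them in the summary, so
  reruns are byte-identical.
- Problem sizes in the shipped tests: permutation checks use 200 runs per
  dataset and 100 null datasets; the null-regime check uses 50 replicates.
  These sizes give stable verdicts for the statistical properties tested
  (binomial/KS bounds are computed at those sizes) while keeping the whole
  suite fast.
- The one worked-example dataset that ships with the package is the set of
  printed single/combination assay values used by the synergy tests; the
  abundance matrix itself is always generated, never stored.

## Known limitations

- Two classes only; no multi-class or orthogonalized PLS variants.
- No external-test-set validation path: with n = 12 the package follows
  the resampling-only validation design, and Q²/permutation results should
  be read accordingly.
- The correlation-cluster construction (components over |r| ≥ t) is one of
  several defensible definitions; cluster counts are threshold-sensitive.
- The exact printed statistics of the motivating study (its R²/Q² triplets
  and PCA variances) depend on a source matrix published elsewhere and are
  out of reach; the synthetic preset reproduces the qualitative regimes
  (high R² with moderate positive Q² and p < 0.05 on filtered data;
  non-positive Q² without class signal), not those numbers.
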
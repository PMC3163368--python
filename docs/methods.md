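# Methods

## Data model

A cohort is a set of spectra on one shared m/z grid (strictly increasing,
positive, in Daltons) with a `cancer`/`control` label per sample.  Grid
identity across samples is required exactly — no interpolation or
resampling is performed, because the intended inputs (protein-chip
SELDI-TOF exports) already share a common grid and resampling would be a
preprocessing decision outside this package's scope.  Intensities are
arbitrary units, finite and non-negative; zero is allowed.

No instrument-level preprocessing (baseline subtraction, calibration,
peak picking) is performed.  The only optional normalization is total ion
current (TIC): each spectrum is rescaled so its intensity sum equals the
cohort median total.  It is never applied implicitly.

## Feature statistic

For every grid point j the two-sample statistic is

    t_j = (X̄_d,j − X̄_c,j) / sqrt(Var_d,j/n_d + Var_c,j/n_c)

with unbiased (n−1) group variances, and two-sided p-values from the
Student t distribution with df = n_d + n_c − 2.  Pairing the
unpooled-variance denominator with the *pooled* degrees of freedom is
deliberate: it matches the convention of classical SELDI profiling
workflows rather than the Welch–Satterthwaite correction a statistician
might otherwise reach for.  With ~100 samples per group the numerical difference is
negligible; with small unbalanced groups Welch df would be preferable,
and users needing it can compute p-values downstream from the exported
`t` column.

Degenerate features are handled explicitly rather than dropped: if both
group variances vanish and the means agree, t = 0 and p = 1; if the
means differ, the feature is an "infinite separation" sentinel
(t = ±inf, p = 0) that outranks every finite |t|.  Ranking is by |t|
descending with ties broken toward the lower m/z, making the permutation
deterministic.  p-values are reported raw; no multiple-testing
correction is applied (the ranking, not a significance cutoff, drives
selection), but the CSV export includes p so users can correct
downstream.

## Discriminatory-subset search

The search looks for k m/z indices (default k = 5) whose joint amplitude
pattern separates the classes.  No single rating of a candidate
pattern's separating power is canonical, so the package defines one: the
leave-one-out nearest-centroid classification accuracy in the
k-dimensional amplitude space, in [0, 1].  A held-out sample counts as
correct only if it is strictly closer to its own class centroid
(recomputed without it); rating 1.0 therefore means the subset fully
discriminates the cohort.  The function is deterministic and
parameter-free, and the registry (`RATING_FUNCTIONS`) is pluggable.

The search itself is an elitist evolutionary loop: `population_size`
(50) random k-subsets; each iteration keeps the `n_elite` (10)
highest-rated, breeds replacements by drawing k distinct indices from
the union of elite indices, and mutates each position with probability
0.1 to a uniformly random feature.  It stops at rating 1.0 or after
`max_iterations` (100).  All hyperparameters are engineering defaults
exposed in `SearchConfig`.  Elitism plus best-ever bookkeeping makes the
per-iteration best-rating log non-decreasing, and on small instances
(20 features, k = 2) the search recovers the exhaustive-enumeration
optimum in ≥ 95% of seeds (asserted in the test suite).  On a full
12,000-point grid a *cold* random start rarely contains an informative
index, so in practice the search is run after t-ranking has reduced the
grid, or on reduced instances; the top-k-by-t selection mode is the
default pipeline path.

## Classifiers

**MLP.**  One hidden layer, default five units, sigmoid activations at
hidden and output layers; single sigmoid output with a 0.5 threshold
(score exactly 0.5 classifies as cancer — documented tie rule).  The
two-class "one against all" scheme degenerates to this single output.
Training is full-batch gradient descent on the mean binary cross-entropy
in its logit-stable form mean(softplus(z) − y·z); backpropagation is
implemented directly and verified against central finite differences.
Defaults: learning rate 0.5, at most 2,000 epochs, stop when the loss
change falls below 1e−6, weights initialised uniform(−0.5, 0.5) from a
seeded generator.  These are engineering choices, all exposed in
`TrainConfig`.  Features are standardized
inside the model with training-set mean/SD (constants stored in the
model document) because raw SELDI intensities span orders of magnitude;
this also makes training accuracy invariant to any common affine
transform of a feature.

**LDA.**  Class means, pooled within-class covariance Σ̂ (scatter divided
by n − 2), priors from class frequencies, discriminant direction
Σ̂⁻¹(μ_d − μ_c), maximum-posterior prediction.  The constraint p < n is
enforced with an explicit error: with at least as many features as
observations the pooled covariance is singular and the rule undefined —
which is precisely why feature selection precedes classification on
spectral data.  An optional ridge term λI with λ = ridge·trace(Σ̂)/p is
available for near-singular cases; by default a singular matrix raises.

## Splitting and metrics

The train/test split draws uniformly without replacement; the training
size is round-half-up(fraction·n), the only rounding consistent with
an 80% split of 216 samples giving 173/43.  Optional stratification
applies the same rounding per class.  Accuracy is A = 100·(1 − N_e/N_b)
(identically 100·(T_p+T_n)/N_b).  Sensitivity Se = T_p/(T_p+F_N) and
specificity Sp = T_n/(T_n+F_p) use their standard epidemiological
definitions, with cancer as the positive class.  Metrics with empty
denominators raise explicit errors, never silent 0 or NaN.  Only the
single 80/20 split protocol is supported; cross-validation schemes,
ROC/AUC curves and bootstrap intervals are out of scope.

## Synthetic cohort generator

Each spectrum is baseline + peaks + noise, clipped at zero:

    y(mz) = B·exp(−λ·(mz − mz_min)) + Σ_p A_p·exp(−(mz − c_p)²/2w_p²) + ε,
    ε ~ N(0, σ²)

Shared peaks have equal class amplitudes; marker peaks differ between
classes by δ = A_disease − A_control.  Gaussian peak shapes and additive
Gaussian noise are the simplest idealizations that exercise the t-test's
normality/equal-variance assumptions; the generator deliberately omits
isotope envelopes, adducts, chemical noise, m/z-dependent resolution,
and intensity heteroscedasticity, so passing tests demonstrate the
pipeline's statistical machinery, not robustness to real instrument
artefacts.  Per-sample noise streams are derived from the seed by
counter offset (`default_rng([seed, i])`), giving bit-reproducible output
independent of generation order; the ground-truth manifest
(`mz_index,mz,delta`) depends only on the configuration, not the seed.

The default configuration emulates the target dataset's structure:
12,000 points over 700–12,000 Da, 95 controls vs 121 cancers, six shared
serum peaks (tallest amplitude 100), and four markers — near 8150 Da and
at 8500/8600/8700 Da inside the 8450–8740 Da window — of width 4 Da.
Marker disease amplitude is 2.0, i.e. 2% of the tallest shared peak,
honoring the observation that the informative features carry at most
~2% of the intensity of the most abundant peaks; the control amplitude
0.5 puts the class gap δ = 1.5 at three noise SDs (σ = 0.5).  These
defaults are the study conditions for all bundled property tests and
for the acceptance script, chosen once as a realistic operating point:
at δ = 3σ with ~100 samples per group the markers' |t| ≈ 20, far above
the null |t| ≈ 2–3 floor of 12,000 comparisons, which is what a usable
biomarker panel requires.

## Pipeline

Stages run in order: acquire (simulate or load) → optional TIC
normalization → feature selection → 80/20 split → train → predict →
evaluate.  Feature selection is fitted on the training half only; the
test half cannot influence which m/z values are chosen.  The
`select_on_all` escape hatch reproduces protocols that selected features
on the full cohort before splitting — it is loudly logged, because on
data of this shape selection leakage can fabricate most of the apparent
accuracy.  Every stochastic stage has its own explicit seed; the
manifest records a SHA-256 digest per artifact, so determinism is
checkable by digest comparison, and a failed stage leaves a manifest
flagging partial outputs.

## Numerical notes and limitations

* The logistic function is evaluated in its two-branch stable form; the
  training loss uses log-add-exp, so extreme logits cannot overflow.
* Zero-variance features during standardization get SD 1 (they carry no
  gradient either way).
* Test-suite problem sizes: the planted-marker recovery study uses the
  full 12,000-point, 216-sample default cohort over 10 seeds; the
  search-vs-enumeration study uses 20-feature instances over 50 seeds.
  These sizes make each study a few seconds of compute while leaving the
  statistical conclusions unambiguous.
* No performance claims are made about the public FDA-NCI ovarian WCX2
  cohort whose structure the generator's defaults emulate: that dataset
  is not bundled, and its exact release is ambiguous.  The
  planted-marker simulation is the package's validation surface instead.
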
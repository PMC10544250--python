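# Methods

This note records the models behind `cytoaging`, the defaults and why they
were chosen, what the synthetic cohort generator does and does not emulate,
and the numerical conventions that make the results reproducible.

## Preprocessing

Per feature, in order: median imputation (imputation value = median of the
observed entries, optionally computed on a designated reference subset),
a shifted log transform, and z-scaling with the sample (n−1) variance.
The log shift is 1 for features whose domain cannot fall below zero
(percentages, intensities, counts); for features that can go negative it is
enlarged to `1 + (−min)` so the smallest log argument is 1 and the log is
nonnegative. The immunological-age path uses imputation and scaling only
(no log), selected by the `log` switch — trajectory analysis works on the
log scale, the age model on the raw scale. A fitted `TransformSpec` is a
pure function: applying it to new subjects never refits, and it serializes
to JSON for exact reapplication. By default scaling moments come from the
full table (matching the original analysis, which scales before
train–test splitting); passing `reference_index` gives the leak-free
variant.

## Trajectories

Each feature is regressed on age with a cubic smoothing spline at 3
effective degrees of freedom — edf meaning the trace of the linear smoother
matrix, the `smooth.spline` convention. The smoother is a B-spline basis
(30 functions, equally spaced knots) with the exact curvature penalty
∫f″(x)²dx; the penalty level is solved by root finding so the trace hits
the target. Linear functions span the penalty null space, so linear
signals are reproduced exactly at any penalty. Predictions clamp to the
observed age range (no extrapolation); the standard evaluation grid is
ages 5–75 at 0.5-year steps, fine enough that crossing counts are stable.

Trajectory vectors are clustered with complete-linkage hierarchical
clustering under the Canberra distance and the tree is cut at four
clusters. Cluster numbering follows descending mean initial trend (mean of
successive grid differences over ages 5–15), making labels deterministic
where dendrogram order is not. Cohort comparison: per-feature shift = grid
mean of (disease − reference); per-cluster two-sided one-sample *t* test of
member shifts against zero (clusters with fewer than two members report a
missing p). Crossing counts use strict sign changes of the trajectory
difference with exact zeros collapsed — a touch without a sign change is
not a crossing. Features whose initial trends disagree between cohorts but
whose trajectories cross at least twice (configurable) are flagged as
sampling variation rather than divergence.

## Immunological age (random lasso)

Chronological age is regressed on the standardized features with a
bootstrap ensemble:

* **Stage 1.** For each bootstrap resample of the training set, a lasso is
  fit on a random feature subset whose size fraction is drawn uniformly
  from `q1_range` (default 0.15–0.20). A feature's initial importance is
  its coefficient averaged over bootstraps with absent features
  contributing zero (the original random-lasso convention; averaging over
  appearances only is available via `absent_as_zero=False`).
* **Stage 2.** A second bootstrap ensemble draws `q2·p` features (default
  q2 = 0.10) without replacement with probability proportional to
  |initial importance| — absolute value, since a negative coefficient is as
  informative as a positive one — and averages the lasso coefficients the
  same way.
* **Outer loop.** Both stages run inside `n_splits` random 80:20
  train–test splits; the final coefficient vector is the average of the
  per-split stage-2 coefficients, and the held-out R² is the per-split test
  R² averaged over splits (the evaluation protocol is not uniquely
  determined; per-split averaging is the package's choice).
* **Cutoff.** Candidate cutoffs span the sorted |importance| values
  (evenly subsampled in rank when numerous). For each of `cv_repeats`
  (default 20) shuffles, 5-fold CV RMSE of an OLS refit on the features
  above each cutoff is computed, and the elbow of the RMSE-vs-cutoff curve
  is the point of maximum perpendicular distance from the chord joining the
  endpoints, with rank spacing on the x axis (importances bunch near zero;
  the knee of interest is where RMSE climbs as real predictors drop out).
  Ties, including a flat curve, resolve to the largest cutoff. The final
  cutoff is the mean of the per-repeat elbows. Features above the cutoff
  form the *retained* (age-predictive) set; the age predictor itself is the
  full averaged coefficient vector — the cutoff labels features, it does
  not zero the model.

The lasso penalty is chosen by minimum-error cross-validation on one
representative bootstrap-plus-subset draw per split per stage and reused
within that split (`alpha_mode="per-bootstrap-cv"` re-solves per bootstrap
at ~100× cost; a fixed `alpha` overrides CV entirely and is what the
oracle-reduction check uses). Defaults are desk scale — 100 splits and 100
bootstraps per stage; `RandomLassoConfig.full_scale()` restores the
original 1000/1000/1000. The whole procedure is a pure function of (data,
config): one `SeedSequence` drives every draw, so importances reproduce bit
for bit.

Ensemble averaging shrinks the prediction slope below 1 (each bootstrap
model sees ~10–20% of features), so a planted acceleration of Δ years is
recovered as roughly slope×Δ; group contrasts are therefore estimated from
the regression of predicted age on chronological age plus a group factor,
which removes age-imbalance noise but not this attenuation. Residual-age
analyses restrict to subjects under an age ceiling (default 30, where the
model is informative), fit the reference regression on the reference
groups, and report standardized multivariable covariate coefficients
(continuous covariates z-scored; binaries unscaled). A piecewise linear
fit of predicted on chronological age with a fixed break at 30 is reported
as a diagnostic.

## Age-centile normalization

Each feature is modeled on the reference population (unaffected CTR+REL by
default) with a distributional regression. Family routing: adjusted
Fisher–Pearson sample skewness > 0.5 routes to the Box–Cox *t* (BCT)
family, otherwise the normal (NO); an explicit override list pins
documented exceptions. Observation weights are 10 for ages < 10, 0.1 for
ages > 70, 1 otherwise (strict inequalities at the boundaries, following
the stated rule), up-weighting the sparsely studied pediatric range.

BCT(μ, σ, ν, τ): z = ((y/μ)^ν − 1)/(νσ) (log form at ν = 0) follows a
Student *t* with τ df, restricted to the z-range attainable for y > 0. The
package implements the exact truncated form by default, so the density
integrates to one and the CDF agrees with quadrature of the density for
every parameter set; the truncation mass is negligible whenever σ|ν| is
small, and `truncation=False` gives the common reference-chart convention.
BCT fits shift the data by `1 − min` when values touch zero.

Parameter curves: location (μ for NO; log μ for BCT) is a cubic spline of
age with df 3, log σ a spline with df 2, ν and τ constant in age. The df
convention counts flexibility beyond the linear trend (total edf = df + 2),
matching the distributional-regression smoothers this configuration is
standard in; df ≤ 0 would be a constant and df = 0 on the scale curve a
log-linear one. The curves are penalized P-splines (12 basis functions for
μ, 8 for log σ) with a second-difference penalty calibrated against the
weighted design so the smoother's trace hits the target edf — a regression
spline with quantile knots instead extrapolates a child-dominated slope
across the sparse, down-weighted old ages and invents trends for null
features. Fitting maximizes the weight-multiplied penalized log-likelihood
jointly over all parameters with L-BFGS-B (moment-based initialization:
weighted penalized ridge for the location curve, constant scale, ν = 0.1,
τ = 10; τ bounded in [0.5, 10⁶]; convergence failure of a weighted fit
falls back to unweighted before raising, mirroring documented practice).

A subject's centile is the fitted CDF of their value at their age, clipped
to [10⁻⁶, 1−10⁻⁶]. Ages outside the fitted range raise unless
`extrapolate=True` clamps to the boundary parameters.

## Group comparison and partition

Age-corrected centiles are compared across the clinical groups with
Kruskal–Wallis (midranks, tie correction) followed by Dunn pairwise
z statistics on the same ranks with the tie term included (centiles can tie
after clipping). Default pairs put the later group of the risk ordering
first ("T1D vs CTR"). The Benjamini–Hochberg family is global over all
features × pairs — the more conservative reading of an ambiguous
protocol — with per-pair adjustment behind `bh_family="per-pair"`. The
feature partition combines a Spearman age screen on the reference groups
(BH FDR < 0.05) with the disease contrast (adjusted p < 0.05); effect sizes
are the Spearman rho and the difference in mean quantile, respectively.

## Disease classifier

Per random 80:20 split: PCA fit on the training portion only (the variant
with a single PCA on all subjects is behind `leaky_pca`), the first 30
component scores fed to an unpenalized logistic regression (small-ridge
fallback on failure), AUROC on the held-out portion; the reported number is
the mean over splits (default 100 splits; the original protocol's 1000 is a
config override). Feature-set arms (uncorrected features, all centiles,
significant centiles) share one seed schedule so identical inputs give
identical AUROCs. Split-averaging does not remove dataset-level spurious
separation, so chance-level checks must also average over datasets.

## Synthetic cohort generator

The generator emulates the cross-sectional structure the pipeline assumes:
ages 2–83 drawn from a truncated two-component normal mixture (defaults
12 ± 4 and 42 ± 12 years, equal weights — pediatric probands plus adult
relatives); group sizes 252/310/24/240 for CTR/REL/RSK/T1D; 172 features in
the four trajectory shapes (66/20/74/12), each shape standardized to unit
variance on the scaled age axis, the upward parabola dipping near age 33;
per-feature amplitudes uniform on 0.2–1.3 so the strongest features reach
feature–age correlations ≈ 0.7 at unit residual noise, matching the strong
adaptive-compartment trends such cohorts show. "Stable" features carry a
weak common upward drift (amplitude 0.08, an order of magnitude below the
age-associated clusters), emulating the slight compositional drift of
innate percentages as adaptive naive compartments contract; exactly flat
features would have no recoverable joint structure under a scale-free
distance. Latent values map to domains: right-skewed intensity features
via a log-normal transform, bounded percentages via a mild logistic squash
(no atoms at 0/100, conditional law near-Gaussian), CBC-like counts
affinely with positive baselines. Disease effects enter as an effective
aging acceleration (default 3 years, applied inside the age-dependent
means) plus per-cluster standardized mean shifts, by default only a 0.3 SD
disease-specific shift on the stable cluster: acceleration already induces
the upward/downward shifts of the age-associated clusters, and adding
shifts there would double-count the effect. Optional hooks: covariate-
linked acceleration (years per SD of a covariate within T1D) and a shared
latent factor for cross-feature correlation (off by default — no value is
asserted for it). Missingness is MCAR at 3% (below the 5.03% per-feature
ceiling such data show); the generator records every mapping constant in
`feature_meta`, so tests can compute oracle conditional centiles.

Not emulated: raw cytometry events, gating, compensation, batch or site
effects, compositional closure among sibling gates, genotypes, and
non-MCAR missingness. Passing tests therefore demonstrate correctness of
the algorithms under the generative assumptions, not robustness to
instrument artifacts.

## Numerical conventions and edge cases

* Sample (n−1) variance everywhere; even-count medians average the two
  middle order statistics; adjusted Fisher–Pearson skewness.
* Retention rule |importance| > cutoff is strict; elbow ties resolve to the
  largest cutoff; degenerate bootstrap draws (constant age) are redrawn.
* Crossing counts collapse exact zeros; initial trend uses the closed
  5–15-year window.
* Centile clipping at 10⁻⁶; weighted-fit fallback to unweighted before
  raising; a stage-2 weight vector with fewer positive entries than the
  draw size is epsilon-smoothed.
* Classifier splits with a single class in either portion are redrawn (at
  most 100 attempts).
* All randomness flows from one integer seed per procedure via
  `numpy.random.SeedSequence`; reruns are bit-identical.

## Problem sizes used in the shipped checks

The validation experiments run at desk scale: 100 outer splits and 100
bootstraps per stage for the random lasso (the original protocol's 1000s
are one config call away), 20 seeds for support recovery and classifier
ordering, 10 for acceleration recovery, 700-subject cohorts (600 fit / 100
held out) for centile calibration, and 50 classifier splits per arm. These
sizes were chosen so the full suite runs comfortably on a laptop while
keeping every Monte-Carlo bound well clear of its noise floor.

## Known limitations

* The immune-age contrast is attenuated by ensemble shrinkage (recovered
  ≈ 0.8 × planted at the default signal strength); the package reports the
  estimator the method defines rather than a debiased variant.
* The planted cluster-1 shift is recovered with a small upward bias
  (~+0.05–0.09 SD): the bounded-domain mappings are not exactly affine, so
  a latent shift is mildly amplified after log/z-scaling on the reference.
* Weighted centile fitting reduces the effective reference size (10×
  weights on ~15% of subjects); held-out KS checks at a few hundred
  subjects sit near the detection boundary of that estimation noise.
* BCT τ is weakly identified for near-lognormal data (the likelihood is
  flat in τ above ~50); fits may return large τ, which is harmless for
  centiles.
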
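# Methods

## Model

Phenotype records are indexed by line j = 1..J and environment i = 1..I:

    y_ij = μ + E_i + g_j + gE_ij + ε_ij

* μ and the environment effects E_i are fixed; E is parameterized as
  sum-to-zero deviations so μ stays identifiable, with a flat prior.
* Line effects g ~ N(0, σ²_g K), where K is a J×J marker-derived kernel.
* G×E effects gE ~ N(0, σ²_gE Ω) with Ω = (Z_E Z_Eᵀ) ⊙ (Z_g K Z_gᵀ):
  records sharing an environment have kernel-structured covariance,
  records in different environments are independent. ⊙ is the Hadamard
  (elementwise) product; Z_E, Z_g are 0/1 incidence matrices of records
  onto environments and lines.
* ε_ij iid N(0, σ²), independent of everything else.

## Kernels

The Gaussian kernel is parameterized on the ρ scale, K_ij = ρ^{d²_ij}
with ρ = e^{-γ} ∈ (0, 1). Marker columns are mean-centered (translation
does not change distances; centering is kept for interface symmetry with
the linear kernel) but not variance-scaled, and squared Euclidean
distances are divided by their off-diagonal mean. The normalization makes
d² an O(1) quantity whatever the marker count, which is what gives a
fixed grid ρ ∈ [0.01, 0.999] meaning; without it, γ would have to chase
the raw distance scale. Degenerate inputs (all lines identical) are
rejected because the normalizer vanishes. The VanRaden genomic
relationship matrix (centered genotype cross-product over 2Σp_k(1−p_k))
is provided as the linear comparison kernel; it errors when every marker
is monomorphic by allele frequency. Kernels are validated symmetric with
smallest eigenvalue ≥ −10⁻⁸ (relative to the largest); anything worse is
an error, never silently clipped.

## Gibbs sampler

Each random effect u = V Λ^{1/2} δ is sampled in the eigenbasis of its
covariance (rank-truncated at 10⁻¹⁰ of the top eigenvalue), where the δ
coordinates are conditionally independent given the other effect block —
the cross-coupling enters only through the m₁×m₂ rotation M = V₁ᵀV₂.
Variances get scaled-inverse-chi-square full conditionals; all
chi-square and normal deviates are pre-drawn from a seeded generator, so
a fit is bit-identical given its seed and the compiled chain is pure
arithmetic.

When every training line is observed exactly once in every environment —
true throughout the line-level CV on crossed designs — the two
covariances are simultaneously diagonalized by the Kronecker basis Q ⊗ U
(U the eigenbasis of the training kernel; Q any orthonormal basis whose
first column is 1/√I): the line-effect covariance is J_I ⊗ K with
eigenvalues I·s_k on the first block, and Ω = I_I ⊗ K. M is then the
selector [I 0] and a Gibbs sweep is O(n). This balanced path and the
general path sample the same posterior; a long-chain test asserts their
agreement, and both are checked against the closed-form oracle below.
The per-iteration loop is numba-compiled; one 3000-iteration fit at
n = 288 records takes ~20 ms, which is what makes replicated nested-CV
experiments affordable on one CPU.

Priors follow the de-facto defaults of Bayesian genomic-prediction
software: df = 5 for every variance, with scales set from prior_R2 = 0.5
of the phenotypic variance split equally between the two genetic terms
(the line-effect scale divided by the mean diagonal of its covariance),
and the mode-matching factor (df+2)/df. Chains default to 6000
iterations, 1000 burn-in, thinning 5; the replicated experiments use
3000/500/5, which the oracle-agreement tests show is ample for posterior
means at these sizes.

## Prediction

Held-out records are predicted by the Rao-Blackwellized conditional
mean: given a draw of the training-record effects, the test-record
effects have conditional mean C_ts C_tt⁺ u_train (pseudo-inverse via the
eigenbasis), a *fixed* linear map of the draw's coordinates — so
averaging over retained draws equals applying the map to posterior-mean
coordinates. Predictions therefore need only the kernel cross-blocks,
and a test record duplicating a training record reproduces that record's
fitted value exactly. Test lines must be in the kernel (genotyped); test
environments must have been seen in training.

`conditional_mean_oracle` is the independent check: the exact Gaussian
conditional mean ŷ_test = m_test + C_ts (C_tt + σ²I)⁻¹ (y − m) at fixed
variance components. On a 30-line dataset with 10 masked records, Gibbs
predictions correlate > 0.99 with the oracle evaluated at the
posterior-mean variances, and the discrepancy shrinks as the chain
grows. The oracle, unlike the finite chain, is exactly equivariant under
joint permutation of lines, and that invariance is tested on it; the
sampler is equivariant in distribution only, because permutation
re-indexes the pre-drawn deviates.

## Tuning strategies

All strategies minimize the inner-CV objective: the outer-training lines
are split into 5 folds; for a candidate ρ the model is fit on 4/5 and
NRMSE computed on the held-out fold; the mean over folds is the score.
The fold partition and the per-fold chain seeds are frozen before any
candidate is evaluated — seeds are keyed by the fold's validation-line
content, so the objective is exactly invariant to fold relabeling — and
are shared by both tuned strategies, making every comparison paired.

* **NT** returns ρ = e⁻¹ with zero evaluations.
* **GrS** evaluates the 26-value grid {0.01, 0.05, …, 0.97, 0.999}
  (25 steps of 0.04 from 0.01, plus the stated endpoint 0.999 as the
  26th value, which honors both the stated bounds and the stated count)
  and selects the argmin, breaking ties toward the larger ρ (the
  smoother kernel). A 13-value half grid (every other value) is used by
  the replicated experiments.
* **BO** fits a Gaussian-process surrogate (constant × squared-
  exponential + white noise, hyperparameters re-estimated each round)
  to the evaluations so far, starting from 5 evenly spaced points, and
  acquires the expected-improvement maximizer on a 1000-point mesh
  (duplicates skipped), up to a budget of 22 evaluations — calibrated
  to cost ~15% less than the grid. The selection is the best point it
  actually evaluated, so it can never return something worse than its
  own best query.

## Nested cross-validation

Folds are assigned to *lines* (7 outer, 5 inner within each
outer-training set), so a genotype never straddles training and testing;
lines nested in environments are stratified by environment via cyclic
assignment over shuffled strata, which also keeps global fold sizes
within one of each other, and every training set retains all
environments (estimability of E_i). Per outer fold: tune on the inner
folds, refit on the whole outer-training set at the selected ρ (refit
seeds shared across strategies), predict the outer-testing records.
Every record is predicted exactly once per strategy.

## Metrics

MSE and NRMSE are computed per outer fold within each scope — each
environment, and "Global" pooling a fold's records across environments —
then averaged over folds with SE = sd/√(folds). NRMSE divides RMSE by
|mean(observed)| of the same scope (the absolute value keeps NRMSE ≥ 0;
trait scales here are positive anyway). Relative efficiencies are ratios
of scope-level mean metrics for the pairs NT/BO, NT/GrS, GrS/BO; they
satisfy RE(A/B)·RE(B/A) = 1 and the chain identity
RE(NT/GrS) = RE(NT/BO)·RE(BO/GrS) to round-off by construction, which
the tests assert on pipeline-produced reports.

## Synthetic data

The generator draws from exactly the model the sampler assumes: allele
frequencies ~ U(0.05, 0.5), genotypes Binomial(2, f) per line
(monomorphic columns redrawn), g from the Gaussian-process prior at a
known bandwidth ρ_true, per-environment kernel-structured gE
(equivalent to the Hadamard covariance on the realized design), iid
noise. Defaults are the reference condition of all replicated
experiments: J = 210, p = 100, I = 2, ρ_true = 0.05,
(σ²_g, σ²_gE, σ²) = (1.0, 0.4, 0.6) — heritability 0.7 exactly — μ = 5
and environment effects ±0.5 on a wheat-yield-like scale. An `additive`
mode replaces the GP draw with g = Gc·β scaled to the same variance, for
experiments where the data hold no bandwidth-specific signal.

Two generator properties matter for interpreting the experiments:

* With independent markers, the relative spread of normalized pairwise
  distances scales as p^{-1/2}. An analytic expected-MSE calculation
  (Gaussian truth, closed-form conditional mean) shows the bandwidth is
  identifiable only when this spread is appreciable: the expected
  penalty of the fixed ρ = e⁻¹ versus the truth peaks (~5%) near
  p = 100 and vanishes as p → ∞, where all unrelated pairs become
  equidistant. p = 100 is therefore the default: it reproduces the
  heterogeneous-relatedness regime of real panels, which achieve it
  through linkage and family structure that iid sampling cannot mimic.
  Real-data gains may be larger because real kinship is far more
  heterogeneous still.
* Bandwidth misspecification is asymmetric: an over-smooth kernel on
  spiky truth still predicts acceptably (similarities stay monotone in
  distance), while an over-spiky kernel on smooth truth discards
  signal. Tests that need a detectable mismatch use the smooth-truth
  direction. Relatedly, as ρ → 1 the kernel becomes affine in d² and so
  emulates the *linear* relationship matrix: on purely additive data,
  tuning legitimately selects large ρ and beats the fixed e⁻¹ — tuning
  gains vanish only when the fixed bandwidth is itself correct, which
  is the ρ_true = e⁻¹ null the tests calibrate against.

What passing synthetic tests do not show: robustness to linkage
disequilibrium, selection, population structure, unbalanced real-world
designs, non-Gaussian traits, or marker-calling noise — none of which
the generator emulates.

## Problem sizes and numerical choices

Replicated experiments run 10 replicates of the reference condition with
the 13-point half grid and 3000-iteration chains (one replicate ≈ 25 s);
the three-strategy head-to-head uses one J = 105 dataset with the full
grid and BO budget 22. The expected tuning gain at the reference
condition is ~3% in global MSE with replicate-to-replicate sd of a
similar size, so single datasets can land on either side of RE = 1;
directional claims are therefore made on win counts over replicates,
and the null calibration (ρ_true = e⁻¹) is asserted on the mean RE.
Eigendecompositions are cached per (kernel, training set) within the
tuning loop. Variance draws are floored at 10⁻¹² and prior scales at
10⁻⁸ so degenerate inputs (e.g. constant phenotypes) stay numerically
stable. Grid/argmin ties break toward larger ρ. PSD checks use −10⁻⁸ on
the smallest eigenvalue; rank truncation uses 10⁻¹⁰ of the largest.

## Known limitations

Single trait only; Gaussian kernel and VanRaden GRM only; REML or
marker-effect (SNP-BLUP) parameterizations are out of scope, as are
record-level folds, leave-one-environment-out CV and multi-dimensional
hyperparameter search. The Global-NRMSE convention (pooled per-fold
denominator) is one of several in the literature; per-environment NRMSE
is reported alongside so either view is available.
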
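# Methods

## Model and notation

The data are an n × p matrix **X** of log-scale expression values with a
two-level group label per sample, dummy-coded as an n × 2 indicator matrix
**D** (groups in lexicographic order; the signed class vector maps the
first group to +1). All fits center the columns of **X** on the training
set and store the centering vector for projecting new data. Group priors
π_g (empirical proportions by default) enter through the diagonal
weighting matrix K with entries π_g / (n_g · n) for a sample in group g;
with balanced groups and empirical priors K is constant and prior
weighting is a no-op, which the tests verify.

### PLS-DA

Each latent component's loading-weight vector is the dominant eigenvector
of the prior-weighted between-group sum-of-squares matrix
B = Σ_g (π_g / n) m_g m_gᵀ, where m_g is the group mean of the (deflated)
centered data. B factors as AᵀA with A the 2 × p matrix of scaled group
means, so the p × p eigenproblem is solved as the 2 × 2 problem on AAᵀ and
back-transformed — the cost per component is O(np), not O(p²). Components
are extracted NIPALS-style: score t = Xw, loading p = Xᵀt/(tᵀt), deflation
X ← X − tpᵀ. New data are projected by replaying the deflation with the
stored weights and loadings, which equals the rotation W(PᵀW)⁻¹ and makes
the leading a columns of a 5-component model identical to an a-component
refit (prefix property; tested to 1e-10).

### Powered PLS-DA

The candidate loading-weight matrix W(γ) has one column per dummy column;
for feature k the entry is

  sign(ρ_k) · |ρ_k|^{γ/(1−γ)} · s_k^{(1−γ)/γ},

with ρ the K-weighted correlation between feature and dummy column and s
the K-weighted feature standard deviation, each column normalized to unit
length. The endpoints are handled by their limiting indicator rules: γ = 0
puts all weight on the feature with the largest s, γ = 1 on the feature
with the largest |ρ| (ties → lowest feature index). At γ = 0.5 both
exponents are 1 and the column is collinear with the covariance weights of
classic PLS, so a fixed-γ = 0.5 powered fit reproduces PLS-DA scores
exactly for two balanced groups (tested to 1e-8).

Per component the final weight is w = W(γ)a with a the leading
canonical-correlation combiner between Z(γ) = X·W(γ) and the dummy block
under K weighting. γ_cc maximizes that canonical correlation over [0, 1]:
bounded scalar minimization (tolerance 1e-4) on the open interval plus the
two endpoint indicator evaluations. A flat objective (spread < 1e-10
across probes and candidates) returns γ = 0.5 flagged.

Numerical choices worth recording:

* Interior-γ powers are evaluated in log space with the column maximum
  subtracted before exponentiation, so extreme exponents (γ near 0 or 1)
  cannot overflow; magnitudes are floored at 1e-300.
* A feature whose standard deviation has been numerically annihilated by
  deflation (s ≤ 1e-9 · max s) has its correlation set to 0: the quotient
  of two rounding errors can otherwise look like a strong correlation and
  capture an indicator column.
* Weight signs are fixed by making the first non-negligible entry
  positive; eigenvectors and canonical directions are sign-ambiguous and
  LDA is sign-invariant.
* The general canonical-correlation computation adds a ridge of
  1e-10 × trace to each within-block covariance (the centered dummy block
  is always rank-deficient). The γ search itself uses the exact two-class
  reduction below, which needs no ridge; value ties at float precision
  (an interior γ whose weights have collapsed onto one feature) resolve to
  the exact endpoint solutions, then to the smaller γ.
* Two-class reduction: the centered dummy block has rank 1 (its second
  column is the negative of the first), so the canonical correlation
  equals the absolute weighted correlation between one candidate
  projection Xu(γ) and the centered indicator, and W(γ)a is proportional
  to the single candidate column u(γ). The cross-validation hot loops use
  this form; a test pins it to the general-path estimator at 1e-10.

### LDA on scores

The terminal classifier on the component scores is pooled-covariance LDA
with empirical class priors (training sets in the harness are balanced, so
these are equal in practice). A ridge of 1e-8 × trace/A is added when the
pooled covariance's condition number exceeds 1e12; exact discriminant ties
go to the first class in sorted order. A cross-check test compares
predictions against scikit-learn's LDA.

## Hyperparameter selection

**γ_PE (the prediction-optimized extension).** On a training set, draw q
random stratified 0.7/0.3 splits (per group, round-half-away-from-zero of
0.7 · n_g samples to the inner training part; the q splits are independent,
so samples recur across splits but never within one). For every γ on the
grid {0, Δ, …, 1} (Δ = 0.1 by default, 11 values) and every split, fit a
fixed-γ powered model with 5 components once and record the inner-test LDA
prediction error using the leading 1…5 components (valid by the prefix
property). Average over splits, take per γ the best component count, and
return the global (γ*, A*) minimizer. Ties resolve to smaller PE, then
fewer components, then smaller γ — parsimony-first and deterministic.
Inner mean PE is split-weighted (every split counts equally) since test
sizes can differ by rounding.

**Component count for PLS-DA, γ_cc and fixed γ.** The same Monte-Carlo
splits, 10 of them, mean PE per component count, argmin with ties to the
fewest components.

## Evaluation harness

Each outer repeat draws a balanced training set: round(0.7 · n_min)
samples per group (n_min the smallest group size; the majority group is
down-sampled), remainder to the test set. For simulated data every repeat
generates a fresh dataset; for file-based data repeats re-split the same
dataset. All methods within a repeat consume the same outer split and the
same inner-split random stream, so equivalent methods see identical
cross-validation segments. Per method and repeat the selected
hyperparameters, the refit on the full outer training set, and the
outer-test prediction error are recorded. Across R repeats the harness
reports mean PE with the Student-t interval mean ± t_{0.975,R−1}·sd/√R
(clipped to [0, 1]) and flags a method pair significant when the intervals
are disjoint. Failed repeats are excluded with the interval's R adjusted,
and always logged. Seeding: one base seed spawns per-repeat substreams
(data, outer split, inner stream), so any single cell of an experiment is
reproducible in isolation.

The t-LDA baseline ranks features by Welch two-sample t-test p-values on
the outer training set, keeps the ten smallest, and runs LDA in that
subspace. The SVM baseline wraps an established linear-kernel
implementation with its cost tuned by stratified 10-fold CV over the
logarithmic grid 10⁻³…10³ (7 points; the choice of grid is this package's
own, as is the 0.7 outer-split fraction used for simulated data — a 0.5
fraction reproducing a half/half split is available as a parameter).

## Simulated data

Features are independent normals. Null features have mean μ₀ (= 0;
immaterial because everything is centered, but exposed as a parameter) and
variance σ_b² + σ_t² identically in both classes; the first 10 of 1000
features are differentially expressed with the class-1 mean shifted by
δ_j, drawn once per dataset. The five cases fix σ_b² = 0.04 and 60 samples
per class and vary σ_t² ∈ {0, σ_b²/4, σ_b²} with δ ~ U[0.1, 0.5] (cases
1–3) or δ fixed at 0.2 / 0.5 with σ_t² = σ_b² (cases 4–5).

What the generator emulates: the high-dimension/low-sample-size geometry,
a realistically small (1%) informative fraction, and biological plus
technical noise on the log scale. What it does not: between-gene
correlation (features are independent, so the condition indexes grow only
weakly — the diagnostics quantify exactly this), heavy tails, batch
structure, or intensity-dependent variance. Passing tests on these data
therefore demonstrate the machinery and its comparative behaviour under
weak collinearity, not performance on strongly collinear expression data.

Diagnostics: condition indexes κ_k = √(λ₁/λ_k) of the feature covariance
(eigenvalues via the n × n Gram matrix when p > n; non-positive
eigenvalues relative to λ₁ report κ = ∞ with a warning) and the absolute
covariances between principal-component scores and the signed class
vector, both series scaled to their maxima, with denominator n − 1.

## Problem sizes used by the tests and the acceptance script

The acceptance script runs the full protocol (100 outer repeats, q = 50,
Δ = 0.1; 25 seeds for the condition-index average). The test suite runs
the same pipelines at reduced sizes chosen once for a desktop budget —
40 repeats/q = 20 for the γ histograms, 30 repeats/q = 10 for the
method-ordering checks, 25 repeats for the (q, Δ) robustness comparison,
20 datasets for generator calibration — and the robustness of the
selection to q and Δ is itself one of the verified claims.

## Known limitations and open choices

* Only two groups are supported end to end; the dummy-coding and
  candidate-matrix shapes keep the g-column structure as an architectural
  hook, but no multi-group path is implemented or tested.
* The γ_PE extension fixes one γ for all components; per-component γ is
  available only through the γ_cc criterion.
* The mean number of components selected by the Monte-Carlo CVs depends
  visibly on how the inner splits are drawn. With the independent-
  partition splits implemented here the inner PE curve rises gently with
  the component count on clean simulated data and selection concentrates
  on 1–2 components; drawing inner training sets with replacement flattens
  the curve and roughly doubles the mean selected count. The partition
  reading is implemented because a 0.7/0.3 partition is internally
  without replacement by definition; the comparative conclusions (the
  prediction-optimized extension uses the fewest components and the
  lowest PE) hold under either reading.
* LDA requires a nonsingular pooled score covariance; perfectly separated
  degenerate score sets (zero within-class variance) raise an error
  rather than being silently regularized.
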
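# Methods

## Model and estimators

**Covariances.** For frames s(t) ∈ R^D, t = 1..N, and spike counts n(t),
the prior covariance C_p is the mean-subtracted covariance over all frames
(1/N normalization) and the spike-triggered covariance C_s is the
count-weighted covariance of spiking frames about the spike-triggered
average (1/N_s).  Population-style 1/N normalization is used rather than
1/(N−1); the choice is configurable in spirit but immaterial to
eigenvectors, which are all the method consumes.  Frames with n(t) > 1
contribute n(t) times, although the bundled simulator is Bernoulli
(single spikes per frame).

**Significance.** The null hypothesis — spiking independent of the
stimulus — is simulated by circular shifts of the spike train: n(t) →
n((t + r) mod N) with r uniform on 1..N−1, preserving the spike count and
the train's internal structure exactly.  An i.i.d. Bernoulli mode at the
empirical rate is available for trains without temporal structure.  R
randomized trains give R·D pooled null eigenvalues (global test: flag
eigenvalues strictly outside the central 1−α interval) or R per-rank
series (nested test).  The nested test only lets the *extremal* ranks
trigger: the largest eigenvalue against the rank-1 upper bound, the
smallest against its rank's lower bound; flagged eigenvectors are
projected out of the frames, C_p is re-estimated, and the analysis
repeats until nothing new is flagged (at most D iterations).  Interior
eigenvalues outside their rank interval are deliberately not flagged —
they are a byproduct of coherent-mode noise.  Ties at a percentile bound
resolve to "not significant" (conservative).

**Formulations.** The *zero-centered* formulation tests ΔC = C_s − C_p
against zero.  The *one-centered* (pre-whitened) formulation multiplies
each mean-subtracted frame by the inverse square root of the sample C_p —
optionally restricted to its top-m eigenpairs (a pseudoinverse of order m,
avoiding noise amplification along low-variance dimensions) — and tests
the whitened C_s against the identity.  When every pseudoinverse order is
scanned, the per-order level is Dunn–Šidák corrected,
α' = 1 − (1 − α)^(1/D).

**The coherent-mode correction.** Natural-scene-like ensembles have an
outstanding leading eigenvalue λ₁ (all-positive eigenvector u₁).  Sampling
theory for the spiked Wishart model gives the sample eigenvalue a bias
ℓ(1 + c/(ℓ−1)) (c = D/N) and variance 2ℓ²(1 − c/(ℓ−1)²)/N; applied to the
spike-triggered covariance (N → N_s) this puts extremal null eigenvalues
of order λ₁·√(2/N_s) into the null band, masking real features whose
eigenvalues are of order the bulk.  The correction projects u₁ (by
default the leading eigenvector of the *sample* C_p — what an experimenter
actually has; a population or externally supplied mode is accepted) out of
every frame and evaluates significance in the (D−1)-subspace, where the
null is governed by λ₂ instead.  The minimal spike count for recovery
scales as λ², so the predicted improvement is (λ₁/λ₂)².  The number of
projected modes is configurable (default 1) in anticipation of strong
secondary modes.

**Restoring coherent components.** Eigenvectors of ΔC are the relevant
features filtered through the stimulus covariance, so a projected-space
eigenvector and its full-space counterpart differ only in their components
along u₁.  Matching maximizes the absolute cosine between non-coherent
component blocks.  Two safeguards: (i) candidates are screened by
eigenvalue — the true counterpart's eigenvalue magnitude is at least the
projected one (restoring the coherent component only adds signal), which
excludes the projected eigenvector's own near-identical "twin" in the full
spectrum; the screen uses a 0.8 slack factor for estimation noise.
(ii) a match below cosine 0.7 is reported as unmatched and the feature is
kept in the projected space, never silently dropped; the union of
full-space and projected-space findings is then the recommended subspace.

**Decorrelation and order selection.** Significant eigenvectors are
multiplied by the pseudoinverse of C_p of order m and renormalized.  With
`pinv_order="auto"` the order is chosen by cross-validation: features are
decorrelated with the training-set C_p, test frames are projected onto
them, and the information between projections and spiking is estimated
from quantile-binned histograms of P(x) and P(x | spike) (15/8/5 bins for
K = 1/2/3 features, coarsened automatically if test spikes are scarce).  A
shuffle-based bias estimate is subtracted — no bias correction is
prescribed by the underlying method; this is this package's choice, and
its standard deviation doubles as the standard error.  The selected m* is
the smallest order within one standard error of the maximum (plateau
rule), conservative when the informative band of orders is broad.
Train/test split is contiguous 3:1, preserving temporal adjacency.

## Model neurons

All cells are LN models with logistic nonlinearities (the
maximum-noise-entropy choice given a mean constraint) applied to stimulus
projections expressed in units of the projection's standard deviation, so
that width w and threshold θ describe matched cells across stimulus
statistics.  Defaults w = 0.5, θ = 2.0, p_max = 1; θ is normally set by
`match_firing_rate`, which solves for the threshold giving a target mean
rate by bracketing + Brent (the rate is strictly decreasing in θ).

- `or2` — two features; p = p_max·[1 − (1−f₁)(1−f₂)] with
  f_i = logistic((|k_i·s|/σ_i − θ)/w): a probabilistic OR, invariant under
  s → −s.  (A sum of sigmoids is not guaranteed ≤ 1; the probabilistic OR
  is the bounded reading of an OR-combination.)
- `mono1` — one feature, monotone: p = p_max·logistic((k·s/σ − θ)/w).
- `coherent1` — same form with k carrying a large coherent-mode component.

Spikes are independent Bernoulli draws per frame (no refractoriness,
bursting, or history dependence).

## Synthetic stimuli

Ensembles are zero-mean multivariate Gaussian, sampled through the
symmetric eigendecomposition square root of the population covariance so
that exactly singular covariances are handled (Cholesky is not).  Three
families:

- `white` — identity.
- `spiked` — eigenvalues (λ₁, λ₂, bulk, …, bulk) with the coherent mode
  u₁ = (1,…,1)/√D; the spiked-Wishart population.  Defaults λ₁ = 50,
  λ₂ = 5, bulk = 1 in the experiment configs (λ₁/λ₂ = 10, the regime of
  interest), λ₁ = 100, λ₂ = 10 in the constructors.
- `powerlaw_spiked` — u₁ with eigenvalue λ₁ over a k^(−γ) tail scaled to
  mean `bulk`: a natural-scene-like heavy tail.  λ₁ must exceed the
  scaled tail's largest value, otherwise the "coherent" mode would not be
  leading and an error is raised.  The orthonormal completion is a
  deterministic Householder basis anchored at u₁ (no hidden randomness).
- `from_file` — any user-supplied D×D matrix (NPZ key "C" or whitespace
  CSV); symmetrized, with eigenvalues in [−1e−10·λ_max, 0) clipped to 0
  and larger violations rejected.

What the generator emulates: the outstanding all-positive coherent mode,
the λ₁/λ₂ separation, and (optionally) a power-law tail.  What it does
not: non-Gaussian higher-order statistics of natural images, spatial
locality/phase structure, temporal correlations between frames, and the
detailed shape of a measured natural-image spectrum (which `from_file`
accommodates).  Passing tests therefore demonstrate correctness of the
estimation machinery under the stated second-order conditions, not
robustness to non-Gaussian structure.

`shuffle_covariance_entries` permutes off-diagonal entries (upper triangle,
mirrored) and diagonal entries separately, preserving the element multiset
and the exact trace.  The shuffled matrix loses positive-definiteness; its
spectrum follows the mean-shifted Wigner semicircle with the outstanding
eigenvalue at D·μ + σ²/μ (μ, σ = element mean, SD) once μ > σ/√D, with the
uniform vector as outlier eigenvector — the same location as the original
outstanding eigenvalue, which is the point of the construction.

## Random-matrix oracles

For aspect ratio c = D/N and unit bulk: the Marčenko–Pastur density with
edges (1 ± √c)²; for a supercritical spike ℓ > 1 + √c the sample
eigenvalue mean ℓ(1 + c/(ℓ−1)), variance 2ℓ²(1 − c/(ℓ−1)²)/N, and limiting
squared eigenvector overlap (1 − c/(ℓ−1)²)/(1 + c/(ℓ−1)).  Below the
threshold, `spiked_eigenvalue_stats` returns the bulk edge with a
`subcritical` flag rather than extrapolating — the formulas are invalid
there and only the supercritical branch is used.  Tracy–Widom edge
fluctuations and other finite-size corrections are out of scope.

## Problem sizes and numerical choices

Experiments default to a desk-scale geometry: D = 48–64 rather than the
16×16 = 256 patch the method targets, with N chosen per grid point as
max(20·D, N_s/0.25) — the second term keeps the Bernoulli firing rate at
or below 25%, since N_s ≤ N for a binary train.  The governing
dimensionless quantities (c = D/N, λ₁/λ₂, N_s scaling) are preserved, so
the masking and correction phenomena are reproduced at these sizes.  Null
distributions use R = 200–300 randomizations in the experiment configs
(R = 1000 is the constructor default); the pooled test requires
α/2 · R · D ≥ 1 and raises otherwise.  The scaling-law benchmark uses
N = 40 000 frames so that the finite-ensemble correction
(1/N_s − 1/N) does not bend the −1 exponent within the fitted range.  The
four-way method-agreement benchmark runs at the family-wise Šidák level
1 − 0.95^(1/D), so the expected number of stray flags across D eigenvalues
is well under one and the count comparison is meaningful.

Eigendecompositions fix signs by making each eigenvector's
largest-magnitude component positive.  Symmetry is validated to 1e−8
relative; PSD violations beyond −1e−10·λ_max are errors.  The coherent1
experiment constructs the feature's non-coherent part along the leading
non-coherent principal component (with a 10% random admixture), mirroring
smooth receptive fields whose energy sits in leading modes; a feature
whose orthogonal part is spread uniformly over a flat bulk carries
vanishing orthogonal-subspace signal (it is suppressed by the square of
the coherent variance share) and is unrecoverable by *any* projected
analysis at realistic spike counts — the union fallback covers that case.

## Limitations

- Gaussian stimuli only; circular-symmetric non-Gaussian ensembles are not
  specifically supported.
- No shrinkage/regularized covariance estimation, no streaming updates.
- Information-based order selection is limited to K ≤ 3 features
  (histogram estimation).
- Eigenvalue debiasing (inverting the spiked-Wishart bias) is not
  implemented; the correction scheme sidesteps rather than removes the
  bias.
- The nested test re-estimates C_p after each projection; variants that
  reuse the original C_p are not provided.
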
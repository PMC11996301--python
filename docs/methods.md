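# Methods

## The problem

Spatial omics assays (spatial transcriptomics spot arrays, MALDI mass
spectrometry imaging) report the expression of many molecules at n planar
tissue locations.  For a pair of molecules (m, m′) — typically a
ligand–receptor gene pair — the question is whether they co-express, and
*where*: a tissue-wide (global) association and a location-specific (local)
association are distinct quantities.  Simple cross-correlation summaries
(bivariate Moran's I, Lee's L, Pearson correlation) confound spatial
autocorrelation of the individual molecules with genuine association
between them: when both molecules are spatially smooth but mutually
independent, the sampling variability of these statistics greatly exceeds
what their permutation nulls assume, and type-I error inflates.  This
package models the association explicitly instead.

## Model

Let X_m(s_k) be the outcome molecule and t_k = t(X_m′(s_k)) a transform of
the predictor molecule at location s_k, with optional covariates C(s_k).
Both regression surfaces vary over space:

- Gaussian model (continuous intensities):
  X_m(s_k) = β₀(s_k) + t_k β₁(s_k) + C(s_k)ᵀα + ε(s_k), ε ~ N(0, σ²).
- Negative binomial model (UMI counts), logit link and constant dispersion:
  η(s_k) = β₀(s_k) + t_k β₁(s_k) + C(s_k)ᵀα,
  p(X_m(s_k)) ∝ (1 − ψ_k)^r ψ_k^{X_m(s_k)},  ψ_k = exp(η_k)/(1 + exp(η_k)).
  The NB mean is r·exp(η_k); r → ∞ recovers Poisson, small r means strong
  overdispersion.

β₀(s) absorbs the spatial autocorrelation of molecule m itself; β₁(s) is
the local co-expression (positive: joint up/down-regulation; negative:
avoidance).  The global summary is the tissue mean β̄₁ = (1/n) Σ_k β₁(s_k).

## Fused horseshoe prior on an MST backbone

Spatial coherence is imposed through the edges of the minimum spanning tree
(MST) of the locations under Euclidean distance.  The MST is acyclic — edge
differences carry no hidden cycle constraints — and gives the sparsest
connected precision structure, so exact O(n) factorizations are possible.
Ties on regular grids are broken by adding a seeded uniform jitter to the
pairwise distances (scale 10⁻⁶ × median distance by default), making the
tree unique and reproducible; for distinct distances the jitter is
irrelevant.

For each surface, edge-wise differences get independent scale-mixture
normals with half-Cauchy local and global scales (σ only under the
Gaussian likelihood):

    β(s_i1) − β(s_i2) | Λ_i, τ, σ ~ N(0, Λ_i² τ² σ²),
    Λ_i ~ C⁺(0, 1),  τ ~ C⁺(0, 1).

The spike at zero fuses similar neighbours (spatial smoothing); the heavy
tails let sharp local changes survive unshrunk.  The prior is intrinsic:
only differences are penalized, and each surface's overall level is
identified by the likelihood (every location carries an observation).

## Gibbs sampler

All updates are conjugate:

- Coefficient blocks.  Each surface's full conditional is Gaussian with
  precision Q = diag(w) + Dᵀ S D, where D is the oriented MST incidence
  matrix, S the diagonal of edge precisions 1/(Λ²τ²σ²), and w the working
  precisions (1/σ² for Gaussian; the Pólya-Gamma weights ω for NB).  Q has
  tree sparsity, so one exact draw costs O(n) via leaf-to-root elimination
  (a sparse Cholesky specialised to trees, numba-jitted); correctness is
  verified against a dense Cholesky oracle in the tests.
- Half-Cauchy scales.  C⁺(0,1) is realized by the inverse-gamma auxiliary
  hierarchy: Λ_i² | aux ~ IG(1, 1/aux_i + d_i²/(2τ²σ²)),
  aux_i ~ IG(1, 1 + 1/Λ_i²); τ² | · ~ IG((p+1)/2, 1/aux_g + Σ d_i²/(2Λ_i²σ²))
  with p = n − 1 edges.  A successive-conditional (Geweke-style) chain over
  (differences, scales) recovers half-Cauchy quantiles in the tests.
- NB augmentation.  ω_k ~ PG(X_m(s_k) + r, η_k) turns the NB likelihood
  into a Gaussian working likelihood with precision ω_k and response
  κ_k/ω_k, κ_k = (X_m(s_k) − r)/2; at fixed ω the NB surface update is the
  Gaussian code path.  The PG draw uses the infinite sum-of-gammas
  representation truncated at 50 terms with the exact mean of the discarded
  tail added back: the mean (b/2z)·tanh(z/2) is then exact and the missing
  variance is O(trunc⁻³).
- Dispersion.  Chinese-restaurant-table augmentation makes the constant
  dispersion conditionally Gamma: r | · ~ Gamma(a₀ + Σ tables,
  b₀ − Σ log(1 − ψ_k)), keeping the sweep fully Gibbs.
- Gaussian variance.  σ² | · is inverse-gamma with contributions from the
  residuals and (because σ enters the prior scale) from both surfaces'
  differences.

Priors where the model family itself names none: σ² ~ IG(0.01, 0.01),
r ~ Gamma(0.01, 0.01), α ~ N(0, 10²) per coefficient — weakly informative
conjugate defaults.

### Predictor transform

Counts enter through t = log1p(X_m′) (matching the log-scale link the
count simulator uses), additionally mean-centred.  Centring matters: with
a free intrinsic intercept surface, a predictor with a large positive mean
aliases the *level* of the slope surface against the level of the
intercept surface; empirically this produced downward-biased, low-power
slope inference, while centring (a pure reparameterization — a constant
slope ν is unchanged) restores unbiased, calibrated inference.  The
Gaussian model standardizes the predictor by default; `identity` is
available for pre-processed inputs.

### Numerical choices

- Scales (Λ², τ²) clipped to [10⁻¹², 10¹²]: half-Cauchy tails overflow
  doubles otherwise.
- The fusion variance entering a coefficient draw is floored at 10⁻⁶
  (edge precision cap 10⁶).  A difference SD of 10⁻³ is numerically exact
  fusion for unit-scale data, and larger edge precisions make the tree
  elimination cancel catastrophically against O(1) working precisions.
  The σ² update applies the same floor for consistency.
- Every coefficient draw adds a diagonal ridge of 10⁻⁷ (prior SD ≈ 3000
  per coefficient): it swamps factorization round-off without influencing
  the posterior.
- PG weights floored at 10⁻¹²; η clipped to ±30 before link evaluations.
- Defaults n_iter = 4000, burn-in = 2000, thin = 2, 95% equal-tailed
  intervals.  The benchmark studies in the tests use 2000/1000/1 chains,
  which mix well here (lag-50 autocorrelation of β̄₁ ≈ 0.01 at n = 293).

## Hypothesis testing

Global: reject H₀: β̄₁ = 0 when the equal-tailed credible interval of β̄₁
excludes zero.  Local: the same per location.  Equal-tailed (rather than
HPD) intervals need no density estimation and are exactly reproducible.
The probability of direction pd — the fraction of posterior draws sharing
the sign of the posterior median, in [0.5, 1] — gives the frequentist-style
p-analog p = 2(1 − pd); with equal-tailed 95% intervals, p < 0.05 and
CI-exclusion of zero coincide up to quantile interpolation.  Across many
screened pairs the global p-values are Benjamini–Hochberg adjusted (the
field-default step-up FDR procedure); local tests are reported raw by
default, with an optional BH flag.

## Simulators

Design 1 (regression truth): Z ~ MVN(0, H) with H = exp(−d/ℓ) (ridge
10⁻⁸), U = Φ(Z) (|Z| clipped at 8.2 to keep U inside (0,1)), X_m′ the NB
quantile transform of U — marginally NB(ψ_m′, r_m′), spatially correlated;
then η = β₀ + ν·log(X_m′ + 1) with β₀ ~ MVN(0, 0.5·H), and
X_m ~ NB(expit(η), r_m).  ν = 0 yields molecules that are exactly
independent yet both spatially autocorrelated — the null that breaks the
geospatial baselines.

Design 2 (copula truth): (Z_m, Z_m′) ~ MVN(0, [[1, ν], [ν, 1]] ⊗ H), each
pushed through Φ and its own NB quantile function; the association is
nonlinear and purely copula-driven.

Default coordinates are a jittered unit-spacing integer grid of n = 293
points (jitter U(−0.1, 0.1), seeded) standing in for a ~300-spot tissue
section; lengthscales are interpreted on that unit spacing.  The study
grids are ℓ ∈ {3.6, 7.2, 18} (design 1), ℓ ∈ {0.6, 1.8, 3.6, 7.2}
(design 2) and ν ∈ {−0.75, …, 0.75}.

What the generator does *not* emulate: library-size variation, zero
inflation beyond NB, segmentation noise, multi-sample structure, or a real
spot layout.  Passing benchmarks therefore demonstrate calibration and
power under idealized NB copula fields, not performance on any particular
tissue.

## Baselines

Simplified reference statistics with two-sided permutation nulls
(p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm), 999 permutations by
default, shuffling one variable's location labels): bivariate Moran's
I = x̃ᵀWỹ/ΣW with Delaunay-adjacency or exponential-kernel weights
(default kernel lengthscale 1.2), Lee's L with k-NN weights (k = 1,
symmetrized by max(W, Wᵀ)), and Pearson correlation.  These are metric
re-implementations, not ports of the original packages.  Under spatial
autocorrelation in both variables the permutation null conditions away the
spatial structure and understates the statistics' true sampling
variability — the classic effective-sample-size problem — which is exactly
the inflation the benchmark measures.

## Validation strategy

- Exact oracles: MST vs spanning-tree enumeration; tree draws vs dense
  Cholesky (mean exactly, moments to Monte-Carlo error); PG mean vs closed
  form; BH vs brute force; toy-arithmetic checks of Moran/Lee/Pearson.
- Distributional: half-Cauchy quantile recovery of the scale chains;
  simulator marginals by chi-square against the NB pmf (on a dispersed
  layout so pooled draws are effectively independent — pooling correlated
  locations would invalidate the chi-square); design-2 latent
  cross-correlation against ν.
- Calibration: simulation-based calibration of the Gaussian block sampler
  on a 30-location tree.  The intrinsic prior has no proper joint to
  simulate from, so the check runs on the proper pinned-root variant (root
  level ~ N(0, v), the sampler adds the matching root precision), with
  scales and σ² fixed; posterior quantiles of the true mean slope are
  tested for uniformity (Kolmogorov–Smirnov).
- End-to-end: type-I error of the global test ≤ nominal + 2 binomial SE on
  50 design-1 nulls (ℓ = 3.6, n = 293, 2000/1000 chains); the geospatial
  baselines inflate on the same nulls with Pearson intermediate; power
  monotone in ν (measured here: 0.04 / 0.28 / 0.88 at ν = 0 / 0.25 / 0.75);
  ≥ 90% CI coverage of ν at 30 locations for both likelihoods (degenerate
  replicates with a constant predictor — which a tiny strongly-correlated
  layout occasionally produces — carry no slope information and are
  excluded from the denominator).

Problem sizes in the test-suite studies (50 replicates per benchmark cell,
100 per coverage cell, 30-location coverage layouts, 2000-iteration
chains) are the package's desk-scale study configuration; the same code
runs larger designs unchanged.

## Known limitations

- One spatially varying predictor; joint bivariate count likelihoods are
  out of scope.
- The spanning tree is fixed up front, not updated during sampling; an
  unfortunate tree can omit informative adjacencies.
- The dispersion CRT update assumes moderate counts (tables are summed
  over every unit); extremely large counts would benefit from an
  approximate table sampler.
- The intrinsic prior leaves surface levels likelihood-identified; with
  all-zero outcomes or constant predictors the slope surface simply
  returns the prior (tests cover both edge cases).
- Power at small |ν| is modest at n ≈ 300 under strong autocorrelation:
  the posterior of β̄₁ legitimately carries the surface's level
  uncertainty.
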
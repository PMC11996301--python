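# spacebf

Bayesian fused spatially varying coefficients (SVC) models for detecting
**local and global spatial co-expression** of molecule pairs in spatial
omics data — spatial transcriptomics UMI counts or continuous mass
spectrometry imaging intensities.  Intended for analysts screening
ligand–receptor (or any molecule) pairs across a tissue section who need
calibrated inference rather than exploratory cross-correlation maps.

## The model

For a pair (m, m′) over n locations s₁,…,sₙ, molecule m is regressed on a
transform t(·) of molecule m′ with location-indexed coefficients:

- Gaussian: X_m(s_k) = β₀(s_k) + t_k β₁(s_k) + C(s_k)ᵀα + ε(s_k)
- Negative binomial (logit link, constant dispersion r):
  η_k = β₀(s_k) + t_k β₁(s_k) + C(s_k)ᵀα,
  p(X_m(s_k)) ∝ (1 − ψ_k)^r ψ_k^{X_m(s_k)}, ψ_k = exp(η_k)/(1 + exp(η_k))

β₁(s_k) is the local co-expression (negative values mean avoidance);
β̄₁ = n⁻¹ Σ_k β₁(s_k) summarizes the tissue.  Each coefficient surface
carries a **fused horseshoe prior** along the edges of the minimum
spanning tree of the locations:

    β(s_i1) − β(s_i2) | Λ_i, τ ~ N(0, Λ_i² τ² σ²),  Λ_i ~ C⁺(0,1),  τ ~ C⁺(0,1)

which smooths neighbouring coefficients while letting sharp local changes
escape shrinkage.  Inference is blocked Gibbs sampling — exact O(n)
tree-structured Gaussian draws, inverse-gamma auxiliaries for the
half-Cauchy scales, Pólya-Gamma augmentation and a conjugate
Chinese-restaurant-table dispersion update for the count model.  The
global test rejects when the equal-tailed credible interval of β̄₁
excludes zero; local tests do the same per location; the probability of
direction pd gives a p-value analog p = 2(1 − pd).

The free spatially varying intercept β₀(s) absorbs each molecule's own
spatial autocorrelation — exactly the confounder that inflates bivariate
Moran's I, Lee's L and Pearson correlation, whose simplified permutation
versions are included for benchmarking (`spacebf.baselines`), along with
the two Gaussian-copula NB simulators used to measure type-I error and
power (`spacebf.simulate`).

## Worked example

```python
import numpy as np
from spacebf import NegativeBinomialSVC, grid_coords
from spacebf.simulate import SimulationSpec, simulate_design1

# a molecule pair with true constant slope 0.75 over 120 grid locations
coords = grid_coords(120, seed=0)
spec = SimulationSpec(design=1, lengthscale=3.6, nu=0.75, seed=42, coords=coords)
x_m, x_mprime, _ = simulate_design1(spec)

est = NegativeBinomialSVC(n_iter=2000, n_burnin=1000, thin=1, random_state=0)
est.fit(x_mprime, x_m, coords=coords)   # sklearn-style: fit, then *_ attributes

res = est.global_test()
loc = est.local_test()
print(f"mean slope     : {res.beta1_bar_mean:.3f}")
print(f"95% CI         : ({res.ci_lo:.3f}, {res.ci_hi:.3f})")
print(f"pd             : {res.pd:.4f}")
print(f"p (two-sided)  : {res.p_two_sided:.4f}")
print(f"significant    : {res.significant}")
print(f"local hits     : {loc.n_significant} / {len(loc.significant)} locations")
```

Output:

```
mean slope     : 0.945
95% CI         : (0.113, 1.664)
pd             : 0.9860
p (two-sided)  : 0.0280
significant    : True
local hits     : 21 / 120 locations
```

The posterior mean slope 0.945 estimates the generative slope 0.75; its
95% credible interval excludes zero, so the pair is declared globally
co-expressed (p ≈ 0.03), and 21 individual locations are locally
significant.  `est.beta1_mean_` holds the fitted slope surface for
mapping, and `spacebf.postprocess` standardizes surfaces, clusters pairs
into spatial patterns, clusters spots into domains, and ranks cell-type
enrichment.

Estimators follow the scikit-learn protocol (`get_params`/`set_params`,
fitted attributes with trailing underscores), and every piece is also
available functionally (`fit_nb_svc`, `fit_gaussian_svc`, `global_test`,
`bh_fdr`, …).

## Command line

```sh
spacebf simulate --design 1 --nu 0.75 --n 293 --seed 1 --out sim/
spacebf screen --counts counts.csv --coords coords.csv --pairs pairs.csv \
               --model nb --iters 4000 --seed 1 --out results/
spacebf benchmark --design 1 --lengthscales 3.6 --nus 0.0,0.5 --reps 50 \
                  --seed 1 --out bench.csv
spacebf postprocess --summaries results/ --k-patterns 3 --k-spots 4 --out post/
```

Expression tables are molecules × locations (CSV/TSV, or MatrixMarket with
`.rows`/`.cols` id sidecars); coordinates are a two-column CSV in the same
location order.  `screen` filters low-expression genes (default: total
reads ≥ round(0.2 × n locations)), fits every listed pair on one shared
MST, and writes per-pair local summaries plus a Benjamini–Hochberg
adjusted global table with a reproducibility metadata sidecar.

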
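# Methods

## Parameters and models

All quantities are identity-by-descent (IBD) probabilities relative to a
named ancestral population *T*. The package distinguishes two matrix forms
of the same relatedness information: **kinship form** (diagonal holds the
self-kinship (1 + f<sub>j</sub>)/2 ∈ [1/2, 1]) and **coancestry form**
(diagonal holds the inbreeding f<sub>j</sub> ∈ [0, 1]); off-diagonals agree.
True-parameter constructors enforce [0, 1] bounds; *estimated* matrices may
contain negative or >1 entries and only symmetry is checked, since the
standard estimator demonstrably produces negative values under structure.

Two data-generating layers are used. The **kinship model** gives genotype
moments `E[x_ij] = 2 p_i`, `Cov(x_ij, x_ik) = 4 p_i (1-p_i) phi_jk`. The
**coancestry model** posits latent individual-specific allele frequencies
(IAFs) π<sub>ij</sub> with `E[pi_ij] = p_i`,
`Cov(pi_ij, pi_ik) = p_i (1-p_i) theta_jk`, and genotypes
`x | pi ~ Binomial(2, pi)`. Under the coancestry model individuals are
locally outbred, so the coancestry diagonal is the structural inbreeding and
the generalized F<sub>ST</sub> is the weighted diagonal mean.

`theta_tilde` (mean between-individual coancestry) is defined by the model
only for uniform weights, `(n theta_bar - F_ST)/(n - 1)`. For general
weights we use the weighted off-diagonal analogue
`(theta_bar - sum_j w_j^2 theta_jj)/(1 - sum_j w_j^2)`, which reduces
exactly to the uniform definition; this generalization is our choice, not a
model requirement.

## Estimators

Every genome-wide estimator is a **ratio-of-means** estimator: numerator and
denominator are summed over loci before one division. This family converges
almost surely to the ratio of expectations as the number of independent loci
grows, with expectation error of order 1/m — the property all consistency
claims rest on. A **mean-of-ratios** variant of the standard kinship
estimator is provided purely for comparison, since that form dominates
practice. For it we follow the prevalent GRM convention: per-locus
`(x_j - 2p)(x_k - 2p)/(4 p (1-p))` off the diagonal and the self-relatedness
form `(1 + [x^2 - (1+2p)x + 2p^2]/(2 p (1-p)))/2` on the diagonal; loci
fixed under the estimated frequency (p̂ ∈ {0, 1}) are skipped and counted.
The plain squared-deviation diagonal is numerically far heavier-tailed at
rare variants; the convention chosen is the one shipped by the major GRM
implementations. Either way the mean-of-ratios form tracks the
ratio-of-means limit several times worse — the ordering, not the exact
distance, is the robust conclusion.

The A-statistic family: `A_jk = mean_i (x_ij-1)(x_ik-1) - 1` is bounded in
[-2, 0] by the dosage bounds and has expectation `(phi_jk - 1) v` with a
single positive nuisance scale `v = (4/m) sum p_i(1-p_i)`. `A_min` is the
minimum, over unordered pairs of distinct subpopulations, of the unweighted
mean of cross-block A values (ties share the same value, so tie-breaking is
immaterial). It consistently estimates −v provided the least-related pair
of subpopulations has zero kinship across it, which pins *T* to the MRCA of
the sample; a non-negative `A_min` is treated as an error (no unrelated pair
identified). `phi_new = 1 - A/A_min` is then consistent for arbitrary
structure. Replacing the minimum with the overall off-diagonal average
gives the Weir–Goudet individual estimator, which targets
`(phi - phi_tilde)/(1 - phi_tilde)` instead of the IBD probabilities.

Classical F<sub>ST</sub> estimators (Weir–Cockerham, Weir–Hill, Hudson
pairwise, HudsonK) are implemented exactly as printed, with their
method-specific frequency weightings (WC/WH weight individuals, HudsonK
weights subpopulations equally). Each has a `_from_freqs` core taking
per-group sample frequencies and sizes; passing all-infinite sizes selects
the printed infinite-sample simplification, under which all three collapse
to the idealized independent-subpopulations estimator — an exact identity
used as a test oracle. The Weir–Hill estimator is written as the single
ratio whose equal-size, large-sample reduction equals the idealized
estimator exactly — the property the tests verify.

Missing genotypes are rejected by all estimators; the I/O layer can drop
incomplete loci at read time (`drop_missing_loci=True`). This keeps
estimator semantics exactly those of the model; pairwise-complete handling
is deliberately out of scope for the estimators themselves.

## Simulators

The simulators define the package's study conditions; their defaults are
the evaluation conditions used throughout: n = 1000 individuals,
m = 300,000 independent loci, K = 10 subpopulations, target
F<sub>ST</sub> = 0.1, ancestral frequencies uniform on (0.01, 0.5),
Balding–Nichols drift `Beta(p(1/f - 1), (1-p)(1/f - 1))` per subpopulation
with differentiations f<sub>u</sub> = (u/K)τ.

* **Independent subpopulations**: random group sizes from a flat Dirichlet
  (rejected below n/(3K), drift-repaired to sum n); per-individual weights
  1/(K r<sub>u</sub>) so F<sub>ST</sub> is the unweighted mean of the K
  subpopulation values; τ = 2K·F<sub>ST</sub>/(K+1) hits the target exactly
  (τ ≈ 0.18 at the defaults). The true coancestry is block-diagonal and the
  bias coefficient is exactly 1/K.
* **1D-geography BN-PSD admixture**: subpopulations at x<sub>u</sub> = u,
  individuals at y<sub>j</sub> = 1/2 + (j−1)K/(n−1); admixture proportions
  proportional to Normal(0, σ) densities of the distances (computed on the
  log scale, so σ → 0 degenerates cleanly to one-hot rows; exact midpoints
  assign to the lower index). σ is found by bracketed Brent root-finding on
  [0.01, 100] (tolerance 1e-6; the bias coefficient is smooth and increasing
  from 1/K there) so that s hits its target — σ ≈ 1.78 for s = 1/2 — and τ
  is then the closed form that yields the target F<sub>ST</sub> (τ ≈ 0.901).
  True coancestry is `Q diag(f) Q^T`; IAFs are `pi = P_sub Q^T` and
  genotypes Binomial(2, π), independent across loci.

What the simulators deliberately do **not** emulate: genetic linkage
(loci are independent, so real-data estimates will be noisier at equal m),
local (family) inbreeding, genotyping error and missingness, and allele
frequency ascertainment. Passing tests therefore demonstrate correctness of
the estimators under the models' assumptions, not robustness to these
real-data features.

A single seeded `numpy` Generator is threaded through all draws; replicate
experiments spawn independent child generators from the master seed.

## Evaluation

Matrix accuracy is summarized as
`100 * RMSE(est, ref) / mean relatedness`, over the unique pairs j < k plus
the diagonal on the inbreeding scale (both matrices converted to coancestry
form first). This entry set reproduces the known accuracy profile of the
estimators at the default study conditions almost exactly; an
`include_diagonal=False` flag exposes the off-diagonal-only alternative.
The scale `phi_mean` is the mean of the reference matrix over the same
entries (≈ 0.05 at the default admixture conditions).

Scalar estimators are evaluated by replicate experiments (structure fixed,
frequencies and genotypes redrawn) and distribution-free order-statistic
prediction intervals: with R sorted estimates, `[X_(j), X_(R+1-j)]` has
confidence `(R+1-2j)/(R+1)`; R = 39, j = 1 gives 95%.

## Numerical choices

* Dense estimators accumulate in locus blocks of 8192 (float64 GEMMs), so
  the full n = 1000 × m = 300,000 evaluation runs in ≈ 4 GB; IAF matrices
  are stored float32 at that scale (the quantization is orders of magnitude
  below sampling noise).
* Test problem sizes: unit tests use n ≤ 100, m ≤ 20,000 shared fixtures;
  the full-scale evaluation (n = 1000, m = 300,000) is exercised once in the
  acceptance tests and in `scripts/acceptance.py`; consistency checks use
  n = 100 with an m-grid up to 100,000. These sizes were chosen so each
  check's Monte-Carlo error is well below the effect it measures.
* Pure-parameter algebra (Wright's partition inversion, form conversions)
  is checked to 1e-10 relative; reference-shift invariance of the limits to
  1e-10 absolute.
* Degenerate inputs: matrices monomorphic under the estimated frequencies
  raise `ZeroDivisionError`; `wright_partition` requires f_local < 1 and
  passes negative structural estimates through unclamped so inconsistent
  inputs remain visible.

## Known limitations

* `A_min` needs subpopulation labels whose least-related pair truly has
  zero cross-kinship; a poor partition biases all kinship estimates by a
  shared scale (upward if the minimum cross-kinship is positive).
* Biallelic, diploid, complete dosage data only; no multiallelic loci,
  polyploidy, or GRM exchange formats of downstream GWAS tools.
* The Weir–Cockerham F_IT estimator and Bayesian (BayeScan-style)
  estimation are not implemented; local inbreeding is accepted as an input
  to Wright's partition but never estimated from genotypes.
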
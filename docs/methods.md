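# Methods

## Model

`gepred` fits the Gaussian linear mixed model

    y = μ1 + X_f β + Σ_r u_r + ε,
    u_r ~ N(0, σ²_r K_r),   ε ~ N(0, σ²_ε I),

where `y` stacks one record per environment × genotype (missing entries
allowed — those records are predicted), `X_f` is an optional full-rank
fixed-effect design, and each `K_r` is a known symmetric positive
semi-definite observation-level covariance kernel. Errors are
homoscedastic by assumption; heteroscedastic residuals, non-Gaussian
traits, and enviromic covariable kernels are out of scope.

### Genomic covariance functions

* **GB** (linear / GBLUP): `K = XX'/p` on the user-supplied marker coding
  (0/1/2 by convention). No implicit column centering is applied — the
  matrix is computed exactly as written; callers who want VanRaden-style
  centering can center `X` first. With `rescale=True` (the default) the
  matrix is divided by its mean diagonal so the average self-relationship
  is 1, keeping kernels from different sources on a comparable scale.
* **GK** (Gaussian): `K_ij = exp(−h d²_ij / q)` with `d²_ij` the squared
  Euclidean marker distance, bandwidth `h > 0` (default 1) and `q` the
  `quantile` (default 0.5, i.e. the median) of the off-diagonal squared
  distances. The quantile is computed over the strict upper triangle with
  linear interpolation: including the structural diagonal zeros would
  bias `q` toward 0 and sharpen the kernel artificially. Markers are not
  standardised before computing distances; standardise `X` beforehand if
  desired. `q = 0` (all genotypes identical) is a degenerate-input error.

External kernels (pedigree, dominance, …) pass through `validate_kernel`,
which symmetrises relative asymmetry below 1e−10 as `(M + M')/2`, rejects
anything worse, and rejects matrices whose smallest eigenvalue is below
−1e−8 × the largest.

### Multi-environment structures

For a phenotype table grouped contiguously by environment, with genotype
incidence `Zu` and environment incidence `Ze`:

| model | random terms |
|-------|--------------|
| SM / MM | main effect `Zu K Zu'` (SM = MM restricted to one environment) |
| MDs   | + single-variance G×E deviation `(Zu K Zu') ∘ Ze Ze'` |
| MDe   | + one kernel per environment, zero outside that environment's block |
| `intercept_random` | + genotype random intercept `Zu I Zu'` |

The Hadamard product with `Ze Ze'` zeroes every cross-environment entry,
so MDs/MDe deviation kernels are built block-by-block and tagged
`block_diagonal`; their off-block entries are exactly zero (bit-exact
with the dense definition, which the tests assert). Contiguous grouping
by environment is **required** and violations fail loudly, because the
block tags and per-block eigen handling are only valid under that
ordering. Unbalanced designs (genotypes absent from some environments)
are supported; blocks are simply smaller. Duplicate (environment,
genotype) records are rejected — replicate plots should be adjusted to
genotype means per environment upstream, the usual practice for this
model class. With `v` base kernels (several Gaussian bandwidths for
kernel averaging, or additive + dominance matrices) every structure is
replicated per base kernel, giving `n × v` terms named `G_1`, `GE_1`, …

## Eigen-rotation and the Gibbs sampler

Each kernel is factorised as `K = U S U'` and eigenvalues ≤ `tol`
(default 1e−10, exposed as a flag) are dropped with their vectors;
truncation also reduces the effective dimension `r` used as the
degrees-of-freedom contribution of that term. Block-diagonal kernels are
decomposed per diagonal block — never materialising the full
decomposition — which is the main computational shortcut for G×E
deviation terms. Rotating a term's partial residual by `U'` makes the
coefficients `b = U'u` conditionally independent univariate normals:

    b_i | ·  ~  N( s_i σ²_u d_i / (s_i σ²_u + σ²_ε),
                   s_i σ²_u σ²_ε / (s_i σ²_u + σ²_ε) ),   d = U' (partial residual)

and `u = U b`. Variances have scaled-inverse-χ² priors, giving draws

    σ² | ·  =  (sum_sq + ν Sc) / χ²(ν + n_eff),

with `sum_sq = Σ b_i²/s_i`, `n_eff = r` for a genetic term and the
residual sum of squares with `n_eff = N` for the error.

One scan, in fixed RNG order: (1) impute each missing phenotype as its
current fitted value plus `N(0, σ²_ε)` noise (data augmentation — keeps
every full conditional univariate and yields predictions for unobserved
records as a by-product); (2) draw `(μ, β)` jointly from the normal full
conditional of least squares on the derandomised residual, flat priors,
covariance `σ²_ε (X̃'X̃)^{-1}` with `X̃ = [1, X_f]` (rank-deficient `X̃`
is an error); (3) update each random term cyclically in kernel-set
declaration order — partial residual, rotated effect draw, then its
variance; (4) draw the residual variance. Gibbs scans are
order-sensitive in finite chains, which is why the update order is fixed
and documented. Initialisation: `μ` at the observed mean, effects at
zero, variances at their prior scales. A single seeded
`numpy.random.Generator` drives every draw, so runs are bit-reproducible
per seed.

Chains of the intercept and all variances are stored at the thinning
interval after burn-in (`floor((ite − burn)/thin)` samples; defaults
1000/200/3); effect vectors are summarised by running posterior means
rather than stored per scan, which keeps memory linear in N.

### Default priors

Degrees of freedom default to 3 for every variance (small enough to be
weakly informative while keeping the prior mean finite). Scales are set
from the observed phenotypic variance so the prior modes partition it
according to `R2` (default 0.5): the residual scale is
`var(y)(1 − R2)(ν+2)/ν` and each of `q` random terms gets
`var(y)(R2/q)(ν+2)/(ν · mean-diag(K_r))`. This is a partition heuristic
in the style of Bayesian whole-genome regression software, not a derived
optimum; with informative data its influence fades, and callers can pass
an explicit `PriorSpec` instead.

## Synthetic data

The generator mirrors a maize multi-environment trial at reduced scale:
a shared panel of genotypes (default fixtures use 50 genotypes × 4
environments, N = 200), 0/1/2 markers drawn Binomial(2, f) with
per-marker allele frequencies uniform in (0.05, 0.5] (Hardy–Weinberg,
monomorphic columns resampled), and phenotypes drawn from exactly the
mixed model above via the same truncated eigen factorisation the sampler
uses (an independent dense multivariate-normal draw is kept in the tests
as a cross-check). Default true variances for demonstration fixtures are
σ²_G = 1.0, σ²_GE = 0.4–0.5, σ²_ε = 0.5 — i.e. broad-sense heritability
around 0.7 with a G×E share of roughly a third of the genetic signal,
typical magnitudes for adjusted means from well-replicated trials.

What the generator does **not** emulate: linkage disequilibrium and
population structure among markers, pedigree relatedness, replicate
plots / experimental-design error recovery, heteroscedastic
environments. Passing tests therefore demonstrate correctness of the
algorithmic machinery under the model's own assumptions, not robustness
to the ways real field data violate them.

## Numerical choices

* Eigen truncation `tol = 1e−10` (absolute); rank-0 kernels are legal and
  contribute a null term.
* PSD acceptance: smallest eigenvalue ≥ −1e−8 × largest; symmetry repair
  only below 1e−10 relative asymmetry.
* `missing_fraction` masks `round(f · N)` records, a deterministic count.
* Variance draws use `chisquare(ν + n_eff)` directly; `ν + n_eff ≤ 0` is
  rejected.
* The sampler asserts the residual bookkeeping identity
  `y* − μ − X_f β − Σ u_r = residual` every scan in `debug` mode.

## Problem sizes used in validation

The test-suite fixtures run at N = 30–200 records with 200–400 markers
and chains of 300–6,000 scans; the closed-form GBLUP comparison uses
5 × 4,000 retained scans at N = 50, the rotated-vs-brute-force
equivalence 5 seeds at N = 30, and parameter recovery 20 replicates of
N = 200 per model. These sizes were chosen so the full statistical
validation completes in well under a minute per property while leaving
Monte-Carlo error comfortably below the tolerances tested.

## Known limitations

* `X_f` must be full rank; no automatic aliasing resolution.
* Only chains of the intercept and variances are stored — Monte-Carlo
  diagnostics for effect vectors are limited to replicate-chain
  comparisons.
* The bandwidth of the Gaussian kernel is not estimated; use a grid of
  bandwidths (kernel averaging) instead.
* Missing-phenotype augmentation assumes records are missing at random.
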
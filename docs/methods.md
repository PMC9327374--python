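# Methods

## Model and assumptions

mvgreml fits the multivariate linear mixed model

    y = Z β + g + e,    Cov(g) = V_G ⊗ A,    Cov(e) = V_E ⊗ I_N,

to T traits measured on N conventionally unrelated individuals, where A is
the genomic-relatedness matrix (GRM) computed from M standardized SNPs and
Z is a block-diagonal fixed-effect design (each trait may have its own
covariate set, encoded in a binary trait-to-covariate map S). The model
assumes: additive SNP effects with equal expected contribution per
standardized SNP (the GCTA-style GRM; GRMs with other SNP weightings, e.g.
LDAK's, are accepted as input and simply reinterpret V_G); joint normality
of genetic values and residuals; and an input GRM already restricted to
unrelated individuals — no relatedness pruning is performed here.

Both variance matrices are parameterized as Gram matrices V = C C' with a
user-specified binary pattern of free vs zero loadings. Consequences:

* V_G and V_E are PSD for every parameter value, so estimated genetic
  correlation matrices are always valid correlation matrices;
* a saturated (lower-triangular) C with T(T+1)/2 free loadings can
  represent any PSD matrix, making the saturated/saturated fit the
  unstructured reference model;
* factor loadings are identified only up to column sign; reported loadings
  normalize each factor's first free loading to be nonnegative (the
  likelihood is unaffected).

Estimation is REML: the likelihood of error contrasts, which removes the
fixed effects from the variance estimation. The implemented objective,
omitting the additive constant, is

    ℓ(θ) = −½ ( log|V| + log|Z'V⁻¹Z| + y'My ),
    M = V⁻¹ − V⁻¹Z (Z'V⁻¹Z)⁻¹ Z'V⁻¹.

## Canonical transform and the O(nT²) kernel

Let A = Q Φ Q' be the GRM eigendecomposition. The data are rotated by the
n = N − L eigenvector columns whose eigenvalues are not among the L
largest; in that basis the covariance is block diagonal with blocks
V_j = d_j V_G + V_E. Removing the L leading principal components both
enables the block structure and absorbs population stratification without
any extra fixed-effect covariates. Default L = 20 (`--adjust-pcs`);
retained zero eigenvalues are kept — those blocks degenerate gracefully to
V_E.

Per parameter value one simultaneous diagonalization is computed: Cholesky
V_E = LL', eigensolve L⁻¹V_G L⁻ᵀ = U Λ U', and W = U'L⁻¹, giving
W V_j W' = d_j Λ + I for every block at once. Log-determinants and all
quadratic forms are then diagonal operations, so a likelihood evaluation
costs O(nT(T+k)) for k covariates.

The gradient uses the REML identity ∂ℓ/∂θᵢ = −½[tr(M ∂Vᵢ) − y'M ∂Vᵢ M y]
with ∂V/∂γ_tf = D ⊗ (e_t c_f' + c_f e_t'). The rank-2 structure collapses
all genetic partials into one T×T accumulator Σⱼ dⱼ([M]ⱼⱼ − rⱼrⱼ') (and an
unweighted one for the environment, with r = My), after which the whole
gradient is two small matrix products — no per-parameter pass over the
data. The average-information matrix AIᵢⱼ = ½ y'M ∂Vᵢ M ∂Vⱼ M y is built
the same way from the vectors sᵢ = ∂Vᵢ r; it is computed once, after
convergence, and skipped entirely under `--no-se`.

A dense implementation that materializes the full NT×NT covariance exists
solely as an independent correctness oracle; the test suite requires
agreement with the block kernel to 1e−8 at L = 0, and checks the gradient
and AI matrix against central finite differences and brute-force M.

## Optimization

BFGS maximization with a golden-section line search. Choices the method
description leaves open, fixed here as package defaults (all overridable):

* convergence when RMS(gradient)/n < 1e−5 — per-observation scaling makes
  the threshold sample-size invariant; `max_iter` 300;
* the inverse-Hessian approximation starts at I/max(1, ‖g‖), so the first
  iteration is a gradient-ascent step with line search;
* line search: bracket doubled while the objective improves (≤20 times),
  then golden-ratio contraction to an interval of 1e−6; non-finite
  objective values (e.g. singular V_E during a trial step) are treated as
  −∞;
* instability handling: a failed line search or non-finite gradient counts
  as an unstable iteration; after 2 consecutive ones the Hessian
  approximation is reset; after 2 resets a single damped AI-Newton step is
  taken — solve (AI + ridge)Δ = g with the ridge doubled and the step
  halved until the likelihood improves — then BFGS resumes;
* curvature-condition failures skip the BFGS update rather than damping it;
* starting values split each transformed trait's variance 50/50 between
  the free diagonal loadings of C_G and C_E, with off-diagonal free
  loadings at 0.1 trait SD (nonzero to break factor sign symmetry) and a
  1% seeded relative jitter, so runs are deterministic given (data, seed).

V_E is required to be positive definite: if its Cholesky fails, one jitter
of 1e−8·mean(diag(V_E)) is added; a second failure aborts with advice to
specify an environmental model closer to saturated. Generalized
eigenvalues are clipped at zero; blocks with d_jλ_t + 1 ≤ 1e−12 raise
rather than silently returning −∞.

## Identification, inference, model comparison

Identification is checked numerically before fitting: the Jacobian of the
half-vectorized (V_G, V_E) with respect to θ must have full column rank at
three random draws, plus structural necessary conditions (free count per
matrix ≤ T(T+1)/2; no duplicated factor columns). This is a local check —
it cannot prove global identification, but it catches the rotation and
permutation symmetries that make factor models unidentifiable in practice.

Standard errors: θ-covariance is the inverse AI matrix at the optimum
(pseudo-inverse with a warning above condition number 1e12), propagated to
h², ρ_G and ρ_E by the delta method with analytic Jacobians (an optional
finite-difference cross-check mode exists). Traits with zero genetic
variance have undefined ρ_G entries, reported as NaN, never as 0. When the
null model places loadings at zero, the χ² reference for the LRT can be
conservative (boundary effect); the standard χ² p-value is reported.

GLS fixed effects β̂ = (Z'V⁻¹Z)⁻¹Z'V⁻¹y are computed per block with the
same whitening, with SEs from the inverse Gram matrix.

LRT between nested models: statistic 2(ℓ_A − ℓ_0), df = difference in
total free-loading counts. Nesting is asserted by the user; a main
log-likelihood below the nested one (beyond 1e−6) is rejected as evidence
of non-nesting or optimizer failure.

## Synthetic-data generator

`simulate_dataset` draws allele frequencies uniformly on [0.05, 0.5],
genotypes Binomial(2, p), standardizes them in sample (dropping
monomorphic columns) and computes the GRM from them. SNP effects are
jointly normal across traits with covariance V_G/M (all SNPs causal by
default — the infinitesimal model implied by GREML; a causal fraction knob
exists), so genetic values have covariance ≈ A·V_G; residuals are jointly
normal with covariance V_E. Per-trait total variance is 1 with
diag(V_G) = target h². Three canned designs: (1) uniform ρ_G (default 0.3)
across 10 traits at h² = 0.5; (2) two clusters of five traits with random
within-cluster correlations (Gram matrices of random unit-norm loading
rows — guaranteed PSD) and exact zeros between clusters; (3) 50
uncorrelated traits. Environmental correlations default to zero
(configurable) for interpretability. Replicates are split from the master
seed via `default_rng([seed, replicate])`, so each (seed, replicate) pair
is independent and byte-reproducible.

What the generator does **not** emulate: linkage disequilibrium, MAF- or
LD-dependent architectures, ascertainment, missingness, and population
structure (the L-PC correction is exercised as an option, not by
simulating confounding). Passing recovery tests therefore demonstrates
correctness of the estimator under its own assumptions, not robustness to
real-data violations of them.

## Problem sizes used in the checks

The validation suite runs at reduced scale, chosen so the whole suite
completes quickly on a laptop-class single core while keeping Monte Carlo
error well inside the asserted tolerances: oracle-equivalence and
derivative checks at N ≤ 40; uniform-correlation recovery with 10
replicates of N=2000, M=2000, T=5 (mean ĥ² asserted within ±0.02 of 0.5 —
the per-replicate sampling SD of ĥ² is ≈ √(2M)/N ≈ 0.032, so the grand
mean over 50 trait-replicates has SE below 0.01); two-cluster structure
recovery at T=6 (clusters of 3) with the between-cluster mean ρ̂_G
asserted within ±0.03 of 0; and LRT calibration from 200 null replicates
at N=400 tested against U(0,1) by Kolmogorov–Smirnov at α=0.01.

## Known limitations

* Memory: the design tensor and AI stack scale as n·T·p and p²·n·T; fine
  for the intended regime (T up to tens, limited covariates), but T≈50
  with many covariates at large N would warrant chunked accumulation.
* One GRM only — no partitioned heritability, no multiple variance
  components beyond (G, E).
* Equality constraints across loadings, correlated factors, and mixture
  χ² boundary corrections are out of scope.
* Complete-case analysis: individuals missing any trait or applicable
  covariate are dropped to keep the Kronecker structure exact.
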
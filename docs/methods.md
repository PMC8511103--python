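# Methods

## Model

For T quantitative traits measured on the same N individuals, stack the
per-trait phenotype vectors trait-major into y (length NT). The model is

    y ~ N( Xβ,  V = V_G ⊗ A + V_E ⊗ I_N )

with A the N×N genomic-relatedness matrix (GRM), V_G and V_E the T×T
genetic and environmental covariance matrices, and X a block-diagonal
design allowing each trait its own fixed-effect set (a shared design is the
special case of T identical blocks). The per-trait SNP heritability and the
pairwise genetic and environmental correlations are deterministic
transforms of V_G and V_E.

Assumptions inherited from the GREML framework: additive SNP effects,
effects homoscedastic on the standardized-genotype scale (so every SNP
contributes equally to heritability under the GCTA weighting; the
LDAK-Thin weighting relaxes this via a frequency term), Gaussian
environmental deviations independent across individuals, and individuals
unrelated enough that A's off-diagonal structure reflects distant
relatedness rather than family structure (hence the pruning step).

## GRM construction

Genotype counts g* ∈ {0,1,2} are standardized under Hardy–Weinberg scaling,
g = (g* − 2f)/√(2f(1−f)), with in-sample allele frequencies f computed over
non-missing calls; missing calls are imputed to 0 on the standardized scale
(the column mean), which keeps the GRM an average over observed SNPs.
The weighted GRM is A = d⁻¹·G·D·G′ for nonnegative per-SNP weights D
summing to d; unit weights recover the common A = M⁻¹GG′. Supported
weightings:

- **gcta** — unit weights (default);
- **ldak-thin** — greedy LD thinning (drop a SNP whose squared correlation
  with a retained SNP within a window exceeds a cap), then weight retained
  SNPs by [2f(1−f)]^(1+α). Defaults r²max = 0.98, window = 100 kb,
  α = −0.25, all exposed as flags;
- **file** — arbitrary user weights.

Relatedness pruning repeatedly drops the individual participating in the
most pairs with relatedness ≥ the cutoff (ties: the later individual in
file order), which is reproducible and near-minimal. Default cutoff when
enabled: 0.025; default MAF filter: 0.01, boundary inclusive.

## Factor parameterization

V_G = C_G·C_G′ and V_E = C_E·C_E′ with lower-triangular T×T loadings. Any
parameter vector therefore yields valid (PSD) covariance matrices, and the
genetic correlation matrix derived from V_G is PSD by construction — the
structural property that stacked pairwise-bivariate estimates lack. The
packed parameter vector θ (length T(T+1)) lists the C_G triangle
column-major, then C_E, and is stable across runs. The full-rank (T-factor)
model is the default; reduced rank is possible by zeroing trailing columns
but is not exposed as a first-class option.

The factorization is sign-degenerate (C and C·diag(±1) give the same V);
the likelihood depends on θ only through V_G and V_E, so this costs nothing
statistically and the reported quantities are invariant.

## Restricted likelihood via the canonical transformation

One eigendecomposition A = P·diag(λ)·P′ (deterministic: descending
eigenvalues, small negatives clipped at zero, eigenvector signs fixed by
their largest-magnitude entry) turns V into N independent T×T blocks after
rotating phenotypes and designs by P′: Σ_j = λ_j·V_G + V_E. The restricted
log-likelihood is

    ℓ_R = −½ [ (NT−K)·log 2π + Σ_j (log|Σ_j| + ỹ_j′Σ_j⁻¹ỹ_j)
               + log|F| − b′F⁻¹b ],

with F = Σ_j X̃_j′Σ_j⁻¹X̃_j and b = Σ_j X̃_j′Σ_j⁻¹ỹ_j accumulating the
fixed-effect (REML) correction blockwise. Fixed effects are handled inside
the restricted likelihood — phenotypes are never pre-residualized, which
would change ℓ_R. One evaluation costs O(N·T³ + N·T·K + K³): linear in N,
cubic in T only through tiny T×T factorizations.

The analytic gradient uses ∂V_G/∂C_G[a,b] = E_ab·C_G′ + C_G·E_ab′, which
collapses to the lower triangles of (Q_G − S_G)·C_G and (Q_E − S_E)·C_E,
where S_G = Σ_j λ_j(Σ_j⁻¹ − W_j), Q_G = Σ_j λ_j e_j e_j′ (unit weights for
the E-part), W_j the REML projector correction and e_j the
precision-weighted residual. No NT-dimensional object is ever formed.

A dense evaluator that builds the explicit NT×NT covariance (guarded to
NT ≤ 600) serves as an independent oracle; the blockwise path matches it to
1e-8 relative over randomized instances, and the analytic gradient matches
central finite differences element-wise.

## Optimization

BFGS on θ with an Armijo backtracking line search (c₁ = 1e-4, shrink 0.5,
up to 60 halvings). A trial point where any Σ_j fails its Cholesky
factorization is infeasible and simply backtracked, so the likelihood is
defined at every accepted iterate. Convergence: max|∂ℓ/∂θ| / (1+|ℓ_R|) ≤
tol, default 1e-5 (implementation-defined; exposed as `--tol`). Hitting the
iteration cap returns the best point seen with a warning rather than an
exception. Initialization residualizes each trait on its covariates and
splits the residual covariance S equally, C_G = C_E = chol(S/2 + εI) with
ε = 1e-4·mean diag(S) — implied starting h² of one half per trait, strictly
feasible, deterministic.

Boundary behaviour: h² → 0 and |r_g| → 1 are reachable (loading columns
may vanish); there are no reparameterization barriers, and near-boundary
standard errors should be treated with caution.

## Standard errors

The observed information is the negative Hessian of ℓ_R at θ̂, formed by
central finite differences of the analytic gradient (step 1e-4·(1+|θ_p|))
— this keeps the advertised complexity and avoids a long closed-form
derivation; it is validated against the across-replicate spread of
estimates in simulation. The parameter covariance is the eigen-clipped
pseudo-inverse (the factorization's sign degeneracy makes the information
legitimately singular along gauge directions; the pseudo-inverse restricts
to the identified subspace). Heritability and correlation SEs follow by the
delta method with analytic Jacobians chained through V = CC′. Wald
two-sided p-values can be formed downstream; the fitter applies no
multiple-testing correction.

A scaling fact worth recording: for a GRM built from M (effectively
independent) markers, the null/weak-signal variance of ĥ² behaves like
2M/N², i.e. SE ∝ √M/N. SEs therefore fall like 1/N at fixed marker panel
and like 1/√N only when marker count grows proportionally with sample size;
the test suite checks the latter regime explicitly (M = 10N).

## Consistency diagnostics

For any square correlation matrix the audit reports the full spectrum and
the count of eigenvalues below −1e-10; for T ≤ 30 an optional scan
evaluates the three-trait statistic r12²+r13²+r23²−2·r12·r13·r23 for every
triple (violation ⇔ statistic > 1 ⇔ a negative eigenvalue in that 3×3
block). `pairwise_bivariate_fit` deliberately reproduces the stacked
pairwise construction so its indefiniteness can be contrasted with the
joint fit, which passes the audit by construction.

Trait clustering uses the Euclidean-compatible correlation distance
d = √(2(1−r_g)) with Ward-D2 agglomeration (the distance convention is a
package choice, exposed as an option); labels are renumbered by first
occurrence for determinism.

## Synthetic data

The simulator draws exactly from the model above: independent SNPs at
Hardy–Weinberg equilibrium (f ~ Uniform(0.05, 0.5) by default), per-SNP
effect vectors with covariance V_G/M on the standardized scale, Gaussian
noise with covariance V_E, and standard-normal covariates with fixed
effects (default two covariates with effects 0.5 and −0.25 per trait).
Everything is deterministic given the seed, end to end.

Named size classes (the study conditions used throughout the tests):

| class | N | M | T | truth |
|---|---|---|---|---|
| tiny | 40 | 100 | 2 | h² = 0.4, r_g = 0.4 |
| small | 500 | 1000 | 3 | h² = 0.4, r_g = 0.4, r_e = 0.15 |
| recovery | 3000 | 5000 | 3 | h² = (0.5, 0.3, 0.2), r_g(1,2) = 0.6, r_g(1,3) = 0.3, r_g(2,3) = 0.2 |

With a finite panel the realized GRM's mean diagonal c = tr(A)/N differs
slightly from 1, so the genetic values carry covariance c·V_G; the truth
record reports both the nominal h² and the c-rescaled effective h² so
recovery checks can target exactly what the data contain rather than
absorbing the rescaling silently.

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent), MAF–effect-size coupling, population stratification,
ascertainment, non-Gaussian noise, and missing phenotypes. Passing
recovery tests therefore demonstrates correctness of the estimator under
its own model assumptions, not robustness to the confounds of real cohort
data.

## Simulation-study design choices

- **Recovery study** (N = 3000, M = 5000, T = 3, 20 replicates): replicates
  share one genotype draw — and hence one GRM eigendecomposition — and
  redraw SNP effects, noise and covariates. REML standard errors condition
  on the realized GRM, so the conditional replicate spread is precisely
  what the 3-SE coverage statement is about; sharing the panel also keeps
  the study inexpensive. Coverage is assessed per estimate (three h² and
  r_g(1,2)) against the effective truth, alongside mean absolute h² bias.
- **Null calibration** (V_G = 0, N = 2000, T = 2, 10 replicates): under the
  null ĥ² is half-normal with SD ≈ √(2M)/N, so the marker count sets the
  noise floor of the check. M = 250 places the 3σ floor (≈ 0.034) below
  the 0.05 line, making the check sensitive to estimator miscalibration
  rather than to panel size.
- **Indefiniteness demonstration**: four strongly and unevenly correlated
  traits (r_g up to 0.9) at N = 200 — the regime where pairwise sampling
  noise routinely pushes stacked matrices outside the PSD cone while the
  joint fit cannot leave it.

## Numerical details and degenerate inputs

- GRM eigenvalues in [−1e-8·λmax, 0) are round-off and clipped to 0; zero
  eigenvalues are retained (those dimensions still carry environmental
  information). Dropping rank-deficient trailing dimensions is reserved for
  explicit user request.
- A singular Σ_j raises a typed error carrying the offending block index;
  the optimizer treats it as an infeasible step.
- Collinear covariates surface as a distinct error from the F-matrix
  Cholesky.
- Monomorphic SNPs (f ∈ {0,1}) cannot be standardized and raise an error
  naming the SNP; the MAF filter (even at threshold 0) removes them and
  all-missing SNPs first.
- Traits fitted to exactly zero genetic variance report h² = 0 and flagged,
  undefined genetic correlations instead of NaN propagation.
- Binary GRM files are little-endian float32, lower triangle including the
  diagonal, row-major — round-trips are exact to float32 resolution.

## Known limitations

- Single variance component: one GRM, no multiple overlapping components,
  no GxE, no sparse-GRM shortcut for very large N (the eigendecomposition
  is O(N³) once, the per-iteration work O(N·T³)).
- The observed information can be indefinite far from a clean optimum; it
  is then eigen-clipped with a warning, and the flag is carried in the fit
  result.
- LD thinning is the only LDAK-style weighting implemented; exact LDAK
  weights are out of scope.
- Phenotypes must be complete cases across all traits analyzed.
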
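# mvgreml

Joint estimation of SNP-based heritabilities and genetic correlations for
many traits from individual-level genotype data — multivariate GREML with a
structural guarantee that the estimated genetic correlation matrix is
positive semidefinite.

## The problem

Genetic correlations across more than two traits are commonly obtained by
running bivariate analyses for every trait pair and stacking the estimates
into a "grand" correlation matrix. Stacked matrices are not constrained to
be valid correlation matrices: for three traits the pairwise estimates must
satisfy

    r12² + r13² + r23² − 2·r12·r13·r23 ≤ 1,

and estimates such as (r12, r13, r23) = (0.9, 0.9, 0.2) violate it
(statistic 1.336 > 1) — no three traits can jointly carry those
correlations. Stacking also misstates standard errors, because each pair is
analyzed as if the other traits did not exist.

`mvgreml` instead fits all T traits jointly in one variance-component
model. For N individuals with genomic-relatedness matrix **A** (built from
M standardized SNPs), the stacked phenotype vector follows

    y ~ N( Xβ,  V_G ⊗ A + V_E ⊗ I_N ),

where V_G and V_E are the T×T genetic and environmental covariance
matrices. Both are parameterized through lower-triangular factor loadings,
V_G = C_G·C_G′ and V_E = C_E·C_E′, so they — and the genetic correlation
matrix R_G derived from V_G — are positive semidefinite at every point the
optimizer visits. Per-trait SNP heritability and pairwise genetic
correlation are read off the fitted components:

    h²(t) = σ_G,tt / (σ_G,tt + σ_E,tt),
    r_g(s,t) = σ_G,st / √(σ_G,ss · σ_G,tt).

The restricted likelihood is maximized by BFGS using closed-form gradients
evaluated blockwise after a one-time eigendecomposition of **A**, so one
evaluation costs O(N·T³ + N·T·K + K³) — linear in the number of
individuals. Standard errors come from the observed information and the
delta method, and reflect the full multivariate structure.

Intended users: statistical geneticists estimating heritability and
genetic-correlation structure across trait panels (e.g. imaging-derived
phenotypes) from biobank-scale individual-level data, and anyone needing an
internally consistent R_G as input to downstream multivariate methods.

## Worked example

Simulate a data set of N = 500 individuals, M = 1000 SNPs and T = 3 traits
with true h² = 0.4 for every trait and true r_g = 0.4 for every pair, then
fit it:

```bash
mvgreml simulate --name demo --size small --seed 42 --out-dir .
mvgreml fit --grm demo/geno --pheno demo/pheno.tsv --covar demo/covar.tsv --out fit
```

The log ends with

```
log-likelihood -1977.637688 after 21 iterations (converged: True)
```

and `fit.HSq.tsv` contains

```
trait   h2        se
trait1  0.262143  0.105367
trait2  0.365921  0.0916239
trait3  0.290735  0.0956462
```

Each heritability estimate is within 1.5 standard errors of the generating
value 0.4 (the exact finite-panel target, 0.3998, is recorded in
`demo/truth.json`). The genetic correlation matrix in `fit.RhoG.tsv`,

```
trait   trait1    trait2    trait3
trait1  1         0.227049  -0.057036
trait2  0.227049  1         0.675135
trait3  -0.057036 0.675135  1
```

scatters around the true 0.4 within its standard errors (`fit.RhoG.SE.tsv`:
0.18–0.29 per pair — N = 500 is a small sample for correlations), and
`fit.audit.json` confirms the structural guarantee: all three eigenvalues
of R_G are positive (`"n_negative": 0`).

To see why joint fitting matters, audit a stacked pairwise matrix carrying
the inconsistent triple above:

```bash
mvgreml check --matrix R.tsv --triples --out chk
# -> "n_negative": 1, triple statistic 1.336, violated: true
```

## Command-line interface

| subcommand | purpose |
|---|---|
| `grm`      | PLINK bed/bim/fam → MAF filter → standardize → (GCTA or LDAK-Thin weights) → GRM, optional relatedness pruning; writes the binary GRM triplet |
| `fit`      | GRM + phenotype/covariate TSVs → joint REML fit, SEs, estimate tables, PSD audit |
| `check`    | eigenvalue + triple-consistency audit of any correlation matrix TSV |
| `simulate` | write a complete synthetic data set with a truth record |

All inputs and outputs use standard formats: PLINK binary genotypes, the
GCTA-style `.grm.bin/.grm.N.bin/.grm.id` triplet, and tab-separated tables
keyed by family/individual ID.

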
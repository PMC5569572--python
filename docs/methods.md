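# Methods

## Model

StepLMM decomposes a quantitative phenotype as

    y = X b + Z q + W g + e,        g ~ N(0, K sigma2_g),   e ~ N(0, I sigma2_e)

where `b` are fixed non-genetic covariate effects (always including an
intercept), `q` are the allele-substitution effects of a small set of
stepwise-selected SNPs treated as *fixed* effects, and `g` is the random
polygenic background with covariance proportional to the realized genomic
relationship matrix `K`. With one phenotypic record per individual the
incidence `W` is the identity, which is what the engine assumes; the
covariance builder accepts a general `W` for completeness. The phenotypic
covariance is `V = sigma2_g K + sigma2_e I`.

The same fitted object answers both questions of interest: the selected
SNPs with their t statistics are the association (GWAS) output, and
`GEBV = Z q + g` is the genomic-prediction output. The GBLUP baseline is
the special case with no SNP fixed effects.

## Kinship

`K` is VanRaden's first construction: dosages centered by twice the
observed (post-MAF-filter) allele frequency, cross-product scaled by
`2 * sum p_i (1 - p_i)`. For an unrelated Hardy-Weinberg population the
diagonal averages ~1. Because the mixed model equations need `K^{-1}`, a
singular sample GRM is "bent" by the smallest diagonal shift from
{0, 1e-6, 1e-4, 1e-2} that pushes the minimum eigenvalue above 1e-8; the
shift is recorded on the object and logged. The eigendecomposition
`K = U diag(lam) U'` is computed once per dataset and reused everywhere:
the stepwise loop changes the fixed-effect design, never `K`.

## REML by spectral decomposition

Rotating `y` and the fixed design by `U'` turns the covariance into the
diagonal `sigma2_g lam_i + sigma2_e`, so REML reduces to a one-dimensional
profile likelihood in `delta = sigma2_e / sigma2_g`. The profile is
evaluated on a 100-point grid over `log10(delta) in [-5, 5]` and refined by
bounded scalar minimization to an absolute tolerance of 1e-6 in
`log10(delta)`; the grid-first strategy protects against local optima. A
boundary optimum is returned with a flag rather than an error. Degenerate
inputs are rejected explicitly: a phenotype lying exactly in the span of
the fixed effects (zero residual), and a kinship that is numerically a
scaled identity (the ratio `delta` is then unidentifiable).

Model selection needs likelihoods that are comparable across different
fixed-effect sets, which REML likelihoods are not. The package therefore
estimates variance components by REML but feeds eBIC the *ML*
log-likelihood evaluated at the REML variance estimates with GLS fixed
effects. This is the standard resolution of the REML/model-selection
conflict; both log-likelihoods are reported on the result object.

## Whitening and the scan

Any factor `L` with `L'L = V^{-1}` satisfies `L V L' = I`, so the
regression of `L y` on `L [X | z]` is an ordinary least-squares problem
whose statistics equal the mixed-model GLS statistics at fixed variance
components. The `whiten` module builds the triangular factor from the
Cholesky decomposition of `V` (by triangular solves, never forming
`V^{-1}`); the stepwise engine uses the mathematically equivalent eigen
factor `diag(d)^{-1/2} U'` with `d_i = sigma2_g lam_i + sigma2_e`, because
re-whitening after every variance-component update then costs only a
diagonal scaling of the pre-rotated data `U' M`. The equality of the two
routes' statistics is asserted by test.

On the whitened scale the errors have unit variance, so adding one SNP
column changes the deviance by exactly the drop in residual sum of
squares: `LRT = RSS0 - RSS1`, chi-square with 1 df. The scan residualizes
`y*` and all candidate columns against `X*` once per iteration (a QR
projection), after which each SNP costs O(n). Candidate columns that are
numerically collinear with the current fixed effects (residual norm below
1e-8 relative) are skipped, not fatal. Ties on the statistic break to the
smaller (chromosome, position), then the smaller column index.

## The stepwise loop

1. REML under the current model (initially the null model).
2. Whiten with the current variance components.
3. Scan all candidates not currently in the model.
4. Tentatively add the top SNP, re-estimate variance components, recompute
   eBIC; if the eBIC does not fall below the best accepted value, revert
   and stop.
5. t-test every in-model SNP except the one just added
   (`t = q / sqrt(sigma2_e C22)`, df = `n_obs - n_beta - n_qtn`, with
   `C22` the q-block diagonal of the inverted MME coefficient matrix); if
   any exceeds `alpha_drop`, drop the least significant one and re-estimate.
6. Repeat until the eBIC cannot decrease, a hard iteration cap (default
   100) is reached, or residual degrees of freedom run out.
7. Solve for the final `b, q, g` and standard errors.

eBIC is the extended BIC `-2 logL + k ln n + 2 gamma ln C(p, k)` with `p`
the number of candidate SNPs after MAF filtering and `ln C(p, k)` computed
via log-gamma. Defaults: `gamma = 1` (the most conservative standard
choice, favoring a low false-positive rate) and `alpha_drop = 0.05`
two-sided; both are configurable. A dropped SNP may re-enter at a later
iteration; re-entries are flagged in the trace. Inside the loop the
solutions and `C22` come from the GLS identities
`sigma2_e C_ff = (F' V^{-1} F)^{-1}` and
`g = sigma2_g K V^{-1} (y - F beta)` in the rotated basis; `solve_mme`
implements the literal three-block Henderson system and the two routes
agree to numerical precision (tested).

## Prediction and variance accounting

`Z` columns are selected-SNP dosages centered by `2p`, so `q` is an allele
substitution effect and the QTL variance `sigma2_q = sum 2 p (1-p) q^2` is
consistent with the coding; centering affects only the intercept. Reported
heritability uses the decomposition
`h2 = (sigma2_q + sigma2_g) / (sigma2_q + sigma2_g + sigma2_e)` with
`sigma2_q` from the detected QTL and `sigma2_g` from the final REML. For
unphenotyped individuals the polygenic part is the kinship regression
`K_{new,train} K_{train,train}^{-1} g_train`, which equals the joint-model
conditional expectation (tested against a dense joint-covariance oracle)
at a fraction of the cost. The closed-form accuracy
`r = sqrt(beta h2 / (beta h2 + Me/N))` with
`beta = sigma2_q / (sigma2_q + sigma2_g)` is provided for study design.

## Synthetic data

The generator emulates a cohort of unrelated individuals: per-SNP minor
allele frequency uniform on [0.05, 0.5], genotypes drawn independently per
SNP under Hardy-Weinberg equilibrium, positions at 2 kb spacing across 5
chromosomes. One trait is controlled by 100 randomly placed QTL with
effect magnitudes from Exponential(rate 1); the true breeding value is the
raw-dosage-weighted effect sum, and a Gaussian residual is scaled to a
target heritability in {0.25, 0.50, 0.75}. Effect signs are randomized by
default (`signed=False` gives the all-positive variant; with independent
SNPs the two are statistically equivalent for every metric here). A
purely polygenic generator (`g ~ N(0, K sigma2_g)`, no major QTL) supports
false-positive studies.

What the generator deliberately does **not** emulate: linkage
disequilibrium, population structure or relatedness, genotyping error and
missingness patterns of real arrays. The absence of LD matters for
interpretation: a selected SNP is either the causal SNP itself or an
unlinked false positive, so exact-position mapping precision is *higher*
here than on real LD-structured genomes, and tests of that metric are
read as lower-bound checks on false-positive control, not as statements
about fine-mapping resolution in real data. Prediction-accuracy
comparisons (stepwise vs GBLUP) are less sensitive to this choice because
both models see the same panel.

## Evaluation metrics

Mapping precision at window `w` kb: a selected SNP is a true hit if a
true QTL on the same chromosome lies within `+/- w` kb (`w = 0` is exact
position identity); each true QTL certifies at most its nearest selected
SNP (ties to the lower position), and precision = hits / n_selected.
Prediction accuracy is the Pearson correlation of GEBV with the true
breeding value; bias is the regression coefficient of true on estimated
values (1 = unbiased). Replicated scenarios report means with standard
errors `sd / sqrt(reps)`.

## Problem sizes and defaults

The replicated benchmark defaults to n = 1000 individuals, m = 5000 SNPs,
100 QTL and 20 replicates per heritability scenario, with one genotype
panel per replicate shared across the three scenarios (the expensive GRM
eigendecomposition and rotation are computed once per panel). These sizes
give stable means (standard errors on h2 of ~0.01-0.03) on a single CPU
desk-scale run. Dense linear algebra throughout assumes desk-scale n (up
to ~10^4); there are no sparse or low-rank shortcuts beyond the single
eigendecomposition reuse.

## Known limitations

- Single trait, single record per individual, additive effects only; no
  dominance, epistasis or interaction scans.
- Dense O(n^2)-memory, O(n^3)-time linear algebra.
- The backward-elimination level `alpha_drop` is a fixed test level, not
  an information criterion; with very many selected SNPs the implicit
  multiple-testing behavior of the drop step is untuned.
- `predict_new` assumes the new individuals were genotyped on the same
  SNP panel; no imputation across panels.
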
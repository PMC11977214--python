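# Methods

## Model and estimation

The core model is the additive multi-environment individual-tree mixed
model described in the README: records from S sites are stacked, each
tree is phenotyped at exactly one site, breeding values follow
`a ~ N(0, Σ_a ⊗ G)` with an unstructured S×S genetic (co)variance `Σ_a`,
and residuals are independent with a per-site variance (`R₀` diagonal —
sites are assessed separately, so residual covariances are not
estimable and are fixed at zero). Fixed effects are genetic-group
(provenance) indicators nested within site, which also absorb the
per-site intercepts.

Because every record maps to a single (tree, site) pair, the phenotypic
covariance matrix has the closed form
`V[i,j] = Σ_a[s_i,s_j]·G[t_i,t_j] + δ_ij·σ²_e[s_i]`, and one restricted
log-likelihood evaluation costs a single N×N Cholesky factorization.
REML maximizes this likelihood by L-BFGS-B on a log-Cholesky
parameterization of `Σ_a` (positive semidefinite by construction — no
post-hoc bending) and log residual standard deviations, with exact
analytic gradients assembled from block sums of `P∘G` and the quadratic
form in `Py`. Boundary estimates are handled by bounding the Cholesky
log-diagonals at a negligible floor (1e-4 of the phenotypic SD scale, ~
1e-8 of variance). Convergence uses the optimizer's relative function
tolerance (1e-8 by default); non-convergence raises. Standard errors
come from inverting the average-information matrix evaluated at the
optimum, and heritability / genetic-correlation SEs by the delta method.
Breeding values and fixed effects solve Henderson's mixed-model
equations with `Σ_a⁻¹ ⊗ G⁻¹` in the random block; the prediction-error
covariance (PEV) block of the coefficient-matrix inverse is returned on
request for the GWAS variances.

## Genomic relationships

`G = WW′ / 2Σpᵢ(1−pᵢ)` with `W = M − 2p`. Allele frequencies for both
the centering and the denominator are the observed (pre-imputation)
frequencies of the analyzed cohort. Monomorphic loci contribute zero
columns to `W` and are excluded from the denominator (avoiding 0/0).
Because centered columns sum to zero, the raw `G` always annihilates the
ones vector and is singular; the default identity blend
`(1−w)G + wI` with `w = 0.01` restores invertibility for the mixed-model
equations (configurable; `w` as small as 1e-6 suffices when `m > n`).
Missing genotypes are mean-imputed per locus; variant filters default to
a 30% missing-rate ceiling and minor-allele count ≥ 1, which also drops
every monomorphic SNP. Pedigree screening compares each pair's realized
relationship against the half-sib expectation (0.25 same-family, 0
cross-family), flags deviations beyond a tolerance (default 0.15), and
derives a deterministic greedy removal set — repeatedly dropping the
tree in the most conflicts — as a reproducible stand-in for manual
parentage curation.

## GWAS back-solution

Marker effects are the linear transformation
`ĝ = λ W′ G⁻¹ â_s` of a site's breeding values, `λ = 1/2Σpᵢ(1−pᵢ)`, and
their sampling variances use `Var(â_s) = G σ²_a,s − PEV_s`:
`Var(ĝ_k) = λ² w_k′ G⁻¹ Var(â_s) G⁻¹ w_k`. The variance expression
lives behind a single function so an alternative (e.g. one ignoring the
PEV) can be swapped in and compared; non-positive computed variances are
flagged as missing rather than silently clamped. The two-sided normal
p-value is computed as `2(1 − Φ(|ĝ|/sd(ĝ)))`; the absolute value makes
the formula genuinely two-sided for negative effects (without it the
expression would exceed 1). Bonferroni thresholds divide α by the number
of markers — not markers × traits × sites — and suggestive tiers default
to 10× and 100× the Bonferroni p. For 467,224 markers at α = 0.05 this
gives −log₁₀ thresholds 6.97 and 4.97. Manhattan coordinates are marker
ordinals (no genome anchoring is assumed); QQ expected quantiles are
`−log₁₀((rank−0.5)/m)`. Spearman rank concordance of per-site p-values
uses average ranks for ties.

## Cross-validation

Folds partition phenotyped trees uniformly at random (sizes differing by
at most one, reproducible from the seed, drawn jointly over sites by
default). Variance components stay fixed at the full-data estimates
across folds; each fold's mixed-model equations are re-solved with the
validation phenotypes removed, and validation trees are scored at their
own site. Predictive ability divides the full-vs-validation correlation
by √ĥ² of the trait-site (the Legarra-style adjustment; a multiply
option exists behind a flag), and is deliberately not clipped at 1.
Dispersion bias is the OLS slope of full-data on validation breeding
values. Site differences are assessed by one-way ANOVA over fold
replicates (k replicates per trait-site) followed by Tukey's HSD at
α = 0.05 with a compact letter display.

**A caution on the √h² adjustment.** For validation trees the
cross-validated prediction is the conditional expectation of the
full-data prediction given the training records, so
`cor(â_full, â_cv) = √(Var(â_cv)/Var(â_full))` — the share of full-data
information already present in training. That share *shrinks* as
heritability grows (the own phenotype gains weight), and dividing by
√ĥ² amplifies the effect because ĥ² sits near its boundary for weakly
heritable traits. Under the simulator the divided PA is therefore not
monotone in simulated h² — it can exceed 1 and is largest for the least
heritable trait — whereas the accuracy against *true* breeding values,
and the multiply-adjusted PA, both increase with h² as expected. The
test suite asserts the true-BV monotonicity and documents (as an
expected failure in the current design) that the divided PA does not
share it.

## Average G×E variance

The per-pair interaction variance is the heterogeneity-plus-correlation
decomposition `v_ij = (σ_a,i − σ_a,j)²/2 + σ_a,i σ_a,j (1 − r_ij)`
(σ_a,s the per-site additive SDs); the summary is the mean over site
pairs, also expressed as a percentage of the mean phenotypic variance.
The pair formula is a stated stand-in injected through a function
argument, so a different definition can be swapped without touching the
callers.

## Phenotype pre-adjustment

Ring indices: drought resistance is drought-year basal-area increment
(BAI) over the mean BAI of the baseline years; sensitivity is classical
dendrochronological mean sensitivity, the average of
`|2(b_t − b_{t−1})/(b_t + b_{t−1})|` over consecutive years. Log
transforms use the natural log. Design adjustment fits, per trait-site,
intercept + replication + maternal family + residual (replication and
family random by default; the family term is the half-sib stand-in for a
full pedigree model at this step), subtracts the replication-effect BLUP
from each record, and reports the replication share of total variance; a
fixed-effect option estimates centered block means by OLS instead.
Gas-exchange traits get a two-step covariate correction per site: OLS on
vapor-pressure deficit (optionally its log), then regression of the
residuals on the VPD-orthogonalized hours-after-sunrise, re-centered to
the site mean. Standardization z-scores each trait, pooled over sites by
default (between-site location/scale differences are left to the
model's site-specific fixed effects); a per trait-site scope is
available by flag.

## Synthetic trials

The simulator emulates an open-pollinated multi-site progeny test.
Defaults: 30 maternal families from 10 provenances, offspring (8, 4, 8)
per family at three sites (600 trees), six replications per site, 2,000
unlinked SNPs with allele frequencies uniform on [0.05, 0.5] (mirrored),
20 QTLs, per-site additive variance 0.5, pairwise genetic correlation
0.8, residual variance 0.5 (h² = 0.5 per site), provenance and
replication effect SDs 0.3. Mothers are drawn from Hardy–Weinberg
equilibrium; each offspring combines one maternal gamete with a gamete
from a fresh unrelated pollen parent, so families are strictly maternal
half-sib (expected relatedness 0.25). QTL effect vectors are
multivariate normal across sites, scaled by the expected marker variance
so realized per-site additive variances and correlations match the
target in expectation; an infinitesimal mode draws breeding values
directly from `Σ_a ⊗ G` instead. Genotype generation is integer and
bit-stable under a fixed seed.

What the simulator does **not** reproduce: linkage disequilibrium
between markers (off by default, reflecting the fast LD decay of large
conifer genomes; pairwise-LD tooling is exercised on duplicated/derived
columns), genotyping error and missingness mechanisms beyond
missing-completely-at-random, spatial field trends beyond block effects,
selection, or multi-generation pedigrees. Passing tests therefore show
the estimators are correct under the stated model, not that real GBS
data meet the model's assumptions.

## Problem sizes and numerical choices

The suites run at desk scale: REML replicates use 600-tree, 2,000-SNP
trials; the null-calibration check uses 200 trees × 20,000 SNPs; the
SNP-BLUP equivalence oracle 80 trees × 200 SNPs. One REML fit at n = 600
takes on the order of a second. With only 20 QTLs and 30 families a
single replicate's realized heritability and genetic correlation scatter
widely around their targets (the worked example in the README shows
exactly that), so recovery is asserted on means over 20 seeded
replicates. Ties in greedy conflict removal break lexicographically; the
Tukey letter display uses insert-and-absorb; degenerate inputs
(constant traits, all-missing loci, zero-variance predictors, singular
coefficient matrices) raise informative errors rather than propagating
NaNs.
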
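# Methods

This note documents the statistical models the package implements, the
defaults it ships with and why, what the synthetic cohort generator does
and does not emulate, and the numerical choices a maintainer would want
spelled out.

## The analysis in one paragraph

The scientific question is whether common variants in two candidate
synaptic genes (*CNTNAP2*, a neurexin-superfamily member, and *NRXN1*)
are associated with a latent neurodevelopmental outcome, and whether that
association is amplified in children carrying an extra sex chromosome
(47,XXX / 47,XXY / 47,XYY) — the "double hit" hypothesis, under which the
extra dosage of X/Y-homologous synaptic genes (e.g. *NLGN4X/Y*) acts as a
multiplier of otherwise mild autosomal variants. Each gene's SNP set is
collapsed into a single component and tested, by permutation, for its
path to a latent factor built from three phenotype measures (nonword
repetition, a general language factor, a global neurodevelopmental
burden index). The cohort design — an SCT group of ~130 with roughly
half the cases ascertained *because of* developmental problems, and two
twin comparison groups formed by splitting ~185 twin pairs one-per-pair
— shapes everything downstream: ascertainment biases the phenotype
distribution, and twin sharing breaks sample independence unless one
co-twin per pair is analysed.

## GSCA: the structural model and its estimator

Generalized Structured Component Analysis is component-based structural
equation modelling: latent variables are *exact* weighted sums of their
indicators rather than factors with residual indeterminacy. For gene
blocks Z_g (n x m_g standardized dosages) and a phenotype block P
(n x 3 standardized measures):

    gamma_g = Z_g w_g,   var(gamma_g) = 1
    eta     = P v,       var(eta) = 1
    eta     = sum_g a_g gamma_g + e

The estimation criterion is the structural residual variance
f = E[(eta − Σ a_g gamma_g)²], minimized by alternating least squares:

1. **paths** — a = Phi⁻¹ c, the OLS of eta on the components
   (Phi = component covariance, c = component–eta covariance);
2. **gene weights** — for each g, minimize f over w_g subject to the
   unit-variance constraint: the optimum is w_g ∝ S_gg⁻¹ t_g with t_g
   the partial cross-covariance target, rescaled to unit component
   variance and sign-matched to a_g;
3. **outcome weights** — v ∝ S_pp⁻¹ Σ a_g S_pg w_g, rescaled.

Each sub-step exactly minimizes f over its own block under its own
constraint, so f is monotone non-increasing; the implementation raises
if it ever is not (this is asserted on *every* fit, including the
thousands of permutation refits). With a single SNP and a single
measure the model collapses algebraically to the Pearson correlation,
which the tests check to 1e-10 — a useful canary for the constraint
handling.

Everything is computed from the cross-product matrix S = X'X/n, never
from n-vectors inside the loop. This matters for permutation inference:
permuting the phenotype rows only changes the genotype–phenotype block
S_zp, so a refit costs O(m³) with m ≈ 50, and 5000 permutations of the
full two-gene model take seconds.

Numerical choices:

* initialization: equal weights 1/√m_g per block, rescaled — the
  criterion is well-behaved enough that no random restarts are needed,
  and fitting is fully deterministic (seeds drive only permutation
  order);
* convergence: |Δf| < 1e-5 (default), max 1000 iterations; a
  non-converged fit is returned with `converged=False` and a warning,
  never silently;
* sign convention: the outcome component covaries non-negatively with
  its first measure, each gene component with its first SNP; weight and
  path signs are flipped together so the fit is unchanged;
* a ridge of 1e-10..1e-12 stabilizes the small Cholesky/solve steps
  against rank deficiency from near-duplicate SNPs (LD up to r² = 1 is
  legal input);
* zero-variance columns are dropped with a warning before fitting;
  missing dosages are mean-imputed, missing phenotypes exclude the
  sample (complete-case) — both choices are logged in the design object.

## Permutation inference and sequential alphas

p = (1 + #{|a_perm| ≥ |a_obs|}) / (B + 1), per path, with the phenotype
block permuted as a unit. This preserves the LD structure of the
genotype blocks and the intercorrelation of the three measures; the
exchangeability assumption is independence of samples, which the cohort
design satisfies after one-twin-per-pair splitting. Two-sided
comparison is the default (the registered tables report plain
permutation p's); a one-tailed directional variant (more minor alleles →
lower outcome) is a switch. The +1 correction keeps p ≥ 1/(B+1) and the
estimator valid. The two gene paths are tested against pre-registered
sequential levels — 0.05 for the *CNTNAP2* path, then 0.025 for the
*NRXN1* path — applied in declared order by
`sequential_alpha_decision`.

Karyotype subgroup analyses repeat the whole procedure on the SCT cases
*not* ascertained through developmental problems, per karyotype;
subgroups below a configurable floor (default n = 10) are skipped with a
warning rather than producing unstable numbers.

## Genotype QC cascade

Fixed order: sample call rate (≥ 0.95 passes) → sample heterozygosity
(strictly outside mean ± 2 SD removed; bounds computed once on the
input set, not iterated) → SNP Hardy–Weinberg (exact conditional test,
p ≥ 1e-6 passes) → SNP MAF (≥ 0.01 passes) → Mendelian inheritance
errors in trios (rate ≤ 0.01 passes; surviving inconsistent trio
genotypes set missing). Boundary conventions follow the wording
"below 95%" / "less than 1%": exactly-at-threshold values pass.

The HWE test is the exact conditional test (probability of heterozygote
counts at most as probable as observed, given the allele counts),
computed with log-gamma sums. A chi-square approximation is *wrong* at
the 1e-6 threshold with a few hundred samples; the exact test is
validated against an integer-arithmetic enumeration oracle for every
genotype configuration with n ≤ 50. The HWE population can be
restricted to designated samples (the pipeline uses one twin per pair
and excludes trisomy probands, whose autosomal calling context is
atypical) while the filter still applies panel-wide.

A caveat the tests make explicit: ± k SD heterozygosity trimming is not
idempotent on arbitrary data (removing the tail shrinks the SD), so the
cascade's fixed-point property is guaranteed only when outliers are
well-separated — as in the engineered fixtures and in realistic panels
where the het-rate distribution is tight. The cascade is deterministic
and order-dependent by construction.

LD reporting computes pairwise r² (squared Pearson correlation of
dosages, pairwise-complete over missing calls) within each region and
counts distinct pairs above 0.8; SNPs are deliberately *not* pruned for
LD before association, matching the registered analysis.

## Phenotype construction

* **Nonword repetition** — consumed as a scaled score (mean 10, SD 3);
  validated, not transformed.
* **Language factor** — one-factor maximum-likelihood model over four
  subtests (Verbal Comprehension, Oromotor Sequences, Sentence
  Repetition, Vocabulary) fitted on complete cases (≥ 10 required),
  regression (Thomson) scores for everyone with ≥ 2 observed subtests
  using the model-implied covariance of the observed subset. Loadings
  are forced to a single sign (positive = better language). If the ML
  fit degenerates, the first principal component is used and the result
  records `method="pca-fallback"`.
* **Global burden** — supplied, not reconstructed (its construction
  from parental report is ad hoc by design); the pipeline only orients
  it.

`orient_and_standardize` puts all three measures on the same
low = impaired orientation (reflection about the reference mean, which
preserves correlations up to sign) and z-standardizes the language
factor against a reference population — by default the pooled twin
comparison sample, a choice the study leaves open and the function logs.

## Gene-based tests

* **Burden (rare variants, MAF < 0.01)** — per-sample score = proportion
  of rare sites carrying ≥ 1 minor allele, regressed on the phenotype
  (two-sided t). The proportion coding is robust to per-gene variant
  count; allele-count coding is a switch.
* **Variance component (SKAT-style, MAF ≤ 0.5)** — score statistic
  Q = r' G W² G' r under an intercept-only null, with r the centered
  phenotype and W = diag Beta(MAF; 1, 25) weights (flat optional).
  Under the null Q ~ Σ λ_i χ²₁ with λ the eigenvalues of
  σ̂² · W G' (I − 11'/n) G W. The p-value uses the Liu–Tang–Zhang
  moment-matching approximation (mean/variance/kurtosis matched to a
  (non)central chi-square); an exact Imhof characteristic-function
  inversion is available as `method="imhof"`. With one variant and flat
  weights both reduce exactly to the 1-df chi-square score test, which
  is asserted against an independent closed form.
* **Multiplicity** — the per-SNP Bonferroni threshold for the
  47-SNP x 3-phenotype family is 0.05/141 = 3.55e-4, displayed to two
  significant figures as 0.00035. The uniformity diagnostic (KS +
  decile table) for the per-SNP p-value collection is descriptive only
  and says so: inter-SNP LD and phenotype correlations are not
  corrected for.

## Power simulation

Per replicate: dosage ~ Binomial(2, maf), phenotype = 0.25 ×
standardized dosage + noise scaled to unit total variance, one-tailed
per-allele OLS slope t-test at alpha = 0.05. At the planned n = 150 this
gives ≈ 93% power by simulation (Fisher-z closed form: 92.7%); the
registered report prints 94%, inside Monte-Carlo agreement at the
printed precision.

Ascertainment is modelled two ways, because the design statement —
"the ascertained half has mean phenotype 0.9 SD below the group
average" — does not pin down a mechanism:

* **truncation** (default, and what the cohort generator uses): the
  ascertained fraction is drawn conditional on phenotype < c, with c
  solving φ(c)/Φ(c) = 0.9 so the truncated mean is −0.9 SD. Selection
  depends on the phenotype, hence also attenuates the within-group
  genotype–phenotype slope.
* **mean_shift**: a random fraction is displaced by −0.9 SD
  independently of genotype (pure residual-variance inflation).

Each combines with either analysis mode (ignore the route, or adjust
for it as a covariate). At n = 130, 50% ascertained, 20k replicates the
four modes give ≈ 85.6% (truncation/ignore — the default), ≈ 76.4%
(truncation/adjust), ≈ 83.5% (mean-shift/ignore) and ≈ 89.2%
(mean-shift/adjust); the printed 87% sits inside this mode envelope and
within 3 points of the default. The `maf` default of 0.5 is innocuous:
the standardized slope, not the allele frequency, sets the power.

## The synthetic cohort generator

The real genotypes are not distributable, so the generator exists to
give every downstream stage inputs with the *statistical structure the
analysis assumes*. Defaults are the study conditions: 130 SCT cases
(59/130 ascertained postnatally, shift 0.9 SD on the language measure),
185 twin pairs (1/3 MZ), karyotype mix 42/43/45, a 47-SNP panel split
24/23 across the two regions with MAF ≥ 0.08, six r² > 0.8 pairs in the
CNTNAP2-region block and eight in the NRXN1-region block over an
r² = 0.04 within-region background, and zero gene effect (the study's
null finding).

Mechanisms:

* **Genotypes** — Gaussian copula at the haplotype level: each
  haplotype is a thresholded multivariate-normal draw (threshold
  Φ⁻¹(maf)), each individual the sum of two independent haplotypes.
  The latent correlation for every SNP pair is calibrated by root
  finding through the bivariate-normal orthant probability (Owen's-T
  form, for speed) so the realized dosage correlation matches the
  target √r². Summing two haplotypes makes Hardy–Weinberg exact at
  generation. Jointly infeasible LD targets (non-PSD latent matrix, or
  targets above the Fréchet bound for a MAF pair) are rejected with a
  diagnostic, not silently projected.
* **Phenotypes** — latent = Σ b_g · (gene component) + residual;
  measures = λ_i · latent + noise. The default loadings
  λ = (0.8129, 0.9349, 0.7381) are the *closed-form* solution of
  λ_i λ_j = r_ij for the observed correlation pattern
  (0.76, 0.60, 0.69) — a three-indicator one-factor model is exactly
  identified, so no numerical calibration is needed. Four battery
  subtests are generated from the language measure (loading 0.9) so
  the factor-analysis module has realistic input. `sct_multiplier`
  scales b_g in the SCT group only — the double-hit injection, which
  the downstream pipeline must detect (a tested property).
* **Ascertainment** — truncation sampling against the pool-standardized
  language measure (or the latent factor, by option). The unascertained
  subgroup is drawn *first*, at random: removing a random subset leaves
  the conditional distribution below the threshold unchanged, so the
  ascertained subgroup's mean lands at −0.9 SD exactly in expectation.
  (Selecting the truncated group first and the "random" group from the
  leftovers biases the latter upward — a subtle trap the tests now pin.)
* **Twins** — four parental haplotypes per pair; children inherit one
  maternal and one paternal haplotype, chosen independently per
  chromosome. MZ co-twins share the transmission (genotype rows
  bit-identical); DZ co-twins redraw it (expected IBD 0.5, and the
  realized within-pair dosage correlation ≈ 0.5 is tested). One-per-pair
  splitting is a seeded random assignment, deterministic and disjoint.

What the generator does **not** emulate: the real regions' allele
frequencies and LD (unavailable by design), phenotype sharing between
co-twins beyond genetics (residuals are independent; irrelevant after
one-per-pair splitting, which is the only way twins are analysed),
genotyping-plate artefacts, ancestry structure, and the DAWBA/parental
instruments behind the burden index. Passing tests therefore certify
the *methods* — calibration, invariances, power, error control — on
data satisfying the model's assumptions, not any empirical claim about
the real cohort.

## Problem sizes used by the test suite

The suite scales the study's inference down to keep runs quick while
preserving the quantities being checked: permutation calibration uses
200 replicate null cohorts at n = 500 with B = 500 (the study's tables
use B = 5000, which the pipeline defaults to); power checks use 20k
Monte-Carlo replicates; gene-based type-I calibration uses 500
replicates at n = 1000. The acceptance script recomputes the two design
power figures at 20k replicates.

## Known limitations

* GSCA here covers exactly the registered topology — G ≥ 1 gene blocks,
  one outcome component, no covariates, no multi-factor structural
  layer; it is not a general GSCA implementation.
* Permutation p-values inherit the lattice of (b+1)/(B+1); at B = 500
  the smallest attainable p is ≈ 0.002.
* The heterozygosity filter's fixed-point caveat above.
* The burden/SKAT tests assume an unstructured sample (no kinship
  correction); the pipeline applies them to the full synthetic cohort
  for demonstration, where twin relatedness mildly violates that —
  results are exploratory by design.
* VCF/PLINK readers handle biallelic hard calls only; imputation
  dosages pass through as hard calls or not at all.
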
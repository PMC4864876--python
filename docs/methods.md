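# Methods

This note documents the models, conventions and numerical choices behind
`polycog`, and what its synthetic cohorts do and do not establish about
real data.

## Polygenic scoring

A score at threshold $t$ is built in three stages, always in this order:
harmonize the summary statistics to the panel, select SNPs with $P \le t$,
then LD-prune the selected set.

*Harmonization.* Matching is by variant id. If the panel's counted (ALT)
allele equals the GWAS effect allele the weight is $+\log\mathrm{OR}$; if it
equals the other allele, $-\log\mathrm{OR}$; both cases are also resolved
across a strand flip (base complement). A/T and C/G SNPs are
indistinguishable across strands and are dropped by default (a toggle keeps
them); unmatched or irreconcilable SNPs are dropped. Every exclusion is
logged with a reason, so SNP-count accounting tables can be rebuilt from
the run log.

*Thresholding.* Inclusion is $P \le t$ (at the conventional cut-offs the
difference from strict inequality is untestable; `<=` is fixed and
documented here). Threshold sets are nested by construction.

*Pruning.* The prune is greedy and p-informed (clumping-like): SNPs are
visited in ascending training $P$ (ties by panel position) and kept iff
their dosage $r^2$ with every already-kept SNP within ±`window` panel
positions is at most `r2_max` (defaults 0.25 and 200 SNPs). Visiting by
significance rather than position avoids discarding the stronger-associated
member of an LD pair; plain position-order pruning is available via
`PruneConfig(p_informed=False)`. The window is counted in SNPs, not
distance, because the panel carries no genetic map. On panels small enough
for enumeration the greedy result provably equals the
lexicographically-first maximal admissible set under the visiting order,
and the test suite verifies this on random panels.

*Scoring.* $\mathrm{PRS}_i=\sum_j d_{ij} w_j$ with missing doses imputed by
the Hardy–Weinberg expectation $2p_j$. Standardization (mean 0, SD 1,
ddof=1) makes reported betas standardized regression coefficients and makes
scores invariant to allele recoding (raw scores shift by a constant under
recoding; standardized scores are identical to numerical precision).

## Stratification components

Ancestry covariates are the top principal components of the centred,
variance-standardized dosage matrix, scaled to unit sample variance.
Classical metric MDS on Euclidean dosage distances spans the same subspace;
PCA is used because it is deterministic and cheap. Missing doses are
mean-imputed for component extraction only. Two conventions are fixed for
reproducibility: each component is oriented so its largest-magnitude
variant loading is positive, and the decomposition is taken on the smaller
Gram matrix side (identical subspace, lower cost). Rank deficiency raises
an error naming the achievable number of components.

## Derived phenotypes

The fluid-ability composite is the first unrotated principal component of
the standardized test battery, fitted on complete cases, sign-oriented so
the mean loading is positive (higher = better performance); rows missing
any test are scored missing. Outlier exclusion is a single pass: mean and
SD are computed once and values beyond ±3.5 SD are masked. Single-pass
(rather than iterated) exclusion is the minimal reading of the convention
and is idempotent when nothing is excluded. Point-biserial correlations are
Pearson correlations of the 0/1 status with the continuous trait.

## Association models

Unrelated cohorts use OLS; binary disease history is analysed with the same
linear probability model (logistic regression is available as a toggle but
is not the default). Family cohorts use the univariate mixed model
$y=X\beta+g+e$, $\mathrm{Var}(y)=\sigma_g^2A+\sigma_e^2I$, with $A$ from
the pedigree by the tabular method (founders $A_{ii}=1$;
$A_{ii}=1+\tfrac12 A_{fm}$; $A_{ij}=\tfrac12(A_{jf}+A_{jm})$). Parents
referenced but absent are treated as founders with a warning; cycles are an
error; the matrix is invariant to input row order.

REML estimation eigendecomposes $A=UDU^\top$ once (cached, since one
pedigree serves many trait × threshold models), rotates the model so the
covariance is diagonal, and profiles the restricted likelihood down to
$\lambda=\sigma_g^2/\sigma_e^2$, maximized by bounded scalar search on
$\log\lambda\in[\log 10^{-6},\log 10^{6}]$ with tolerance $10^{-8}$.
Solutions at the bounds — and exactly flat profiles, as with $A=I$, where
the variance split is unidentifiable — are flagged as boundary. With a true
zero genetic variance the REML estimate collapses to the boundary in about
half of replicates (the classical boundary mixture); users should expect
`boundary=True` roughly that often under a null variance component.

Fixed-effect inference is the Wald $z=\hat\beta/\mathrm{se}$ with
$p=2\Phi(-|z|)$. For single-parameter tests at cohort-scale $n$ this is
numerically indistinguishable from a conditional F-test; the z form is used
throughout for cross-model consistency. Standardized betas come from
z-scoring outcome and predictor over the complete cases before fitting
(binary outcomes stay on the 0/1 scale). Collinear designs raise an error
naming the offending columns. Raw p-values are reported with no
multiplicity adjustment; an FDR column can be enabled downstream but is off
by default.

## Meta-analysis

Fixed-effects inverse-variance pooling: $w_i=1/\mathrm{se}_i^2$, pooled
$\mathrm{se}=1/\sqrt{\sum w_i}$. Heterogeneity: Cochran's $Q$ about the
pooled estimate, $\chi^2_{k-1}$ tail probability, and
$I^2=\max(0,100(Q-\mathrm{df})/Q)$. A DerSimonian–Laird random-effects
option adds the moment estimate
$\tau^2=\max(0,(Q-\mathrm{df})/(\sum w-\sum w^2/\sum w))$ to each study
variance; it exists for fidelity to common practice but fixed effects is
the default and the analysis surface. Per-study and pooled confidence
intervals are both emitted in the forest table because either may be
wanted for plotting.

## The synthetic-cohort generator

The generator is first-class, tested code; its defaults define the study
conditions under which the pipeline is validated.

*Genotypes.* Haplotypes come from a block-exchangeable latent-Gaussian
threshold model: within a block of `snps_per_block` SNPs, latent normals
share a factor with weight $\sqrt{\rho}$ (`within_block_rho`, default 0.4)
and are thresholded at the block allele frequency (drawn uniformly on
[`maf_low`, `maf_high`] = [0.05, 0.5] per block, shared within the block so
$\rho=1$ degenerates to identical columns). Blocks are independent, which
is what makes the ±200-SNP pruning window meaningful. A small fraction
(5%) of SNPs get strand-ambiguous allele pairs so harmonization policy is
exercised.

*Families.* Founders receive reference haplotype pairs; each offspring
inherits one whole block-haplotype per block from each parent. Block-level
transmission preserves LD with minimal machinery; there is no within-block
recombination, no recombination map, no X chromosome. Cohorts drawn with
different `draw_tag`s share variant definitions but are independent
haplotype draws from the same population model — this matters: cohorts
sampled from one finite pool would be genetically overlapping, and a
meta-analysis across them would not be pooling independent evidence.

*Disease and pleiotropy.* `n_causal` SNPs (default 150) carry zero-mean
effects scaled so the liability variance explained equals `h2_liability`
(0.4) on a large founders-only architecture panel; disease status is
liability above the $1-K$ quantile ($K=0.25$). The cognitive factor is
$r_g\,\tilde g_{\mathrm{cad}}+\sqrt{1-r_g^2}\,g_2$ with $g_2$ a polygenic
value on disjoint SNPs. Because disease- and cognition-causal SNPs can
share LD blocks, a raw draw of $g_2$ would carry real genetic correlation
even at $r_g=0$; $g_2$ is therefore orthogonalized against the disease
genetic value on the architecture panel, so that $r_g$ alone controls
pleiotropy. One residual effect remains by construction: the *pruned*
score is not proportional to the full disease-effect vector, so with few
independent blocks a per-replicate genetic correlation of order
$1/\sqrt{n_\mathrm{blocks}}$ survives at $r_g=0$. Null-calibration checks
therefore use a genome-like number of independent blocks (60); real
genome-wide scores, with thousands of independent loci, are in that regime.

*Phenotypes.* The factor has heritability `h2_cog` (0.5); the environment
splits into a family-shared part (SD `sigma_family`=0.2 of the unit
environmental SD) and unique noise. Four named tests load on the factor
(loadings 0.85, 0.75, 0.80, 0.70) and carry age and sex effects
(`beta_age`=−0.3, `beta_sex`=0.1 per SD); ages are uniform on [25, 90] so
age-band analyses (<40, 40–60, >60) are exercisable; sexes are balanced.
Latent truth columns (`latent_factor`, `latent_liability`, ...) are emitted
for calibration tests and are never analysis traits.

*Training GWAS.* Observed $\log\mathrm{OR}_j = c\,\beta_j +
\mathcal N(0,\mathrm{SE}_j)$ with
$\mathrm{SE}_j=1/\sqrt{N\,2p_j(1-p_j)K(1-K)}$ and the fixed
liability-to-log-odds constant $c=\varphi(t)/(K(1-K))$, $t=\Phi^{-1}(1-K)$
— the derivative of the liability-to-probability map over the log-odds
derivative. Only rank and sign fidelity of the weights matter to the
pipeline, so this first-order mapping is sufficient; $N$ defaults to
86 995, the scale of a large disease GWAS consortium. Note the training
noise is *shared* by every cohort scored with the same summary statistics;
this mildly correlates cohort-level estimates, a real feature of the
design that shrinks with $N$.

*What the simulator does not emulate.* Genotyping error, imputation
uncertainty, array content differences between cohorts, case
ascertainment, assortative mating, population stratification confounded
with phenotype (subpopulations are available in tests but not coupled to
the traits), age-varying genetic effects, and selection/attrition. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated generative model, not that real-cohort effect
sizes would be recovered.

## Problem sizes used in validation

Simulation-based checks are sized for precision per compute: variance-
component recovery uses $n=2000$ in 200 sibships of 10 (a design with
enough between-family information for a ±0.1 heritability check); power
recovery uses three cohorts of $n=2000$ (one family cohort) at
$r_g=-0.3$ over 50 replicates; null calibration uses three cohorts of
$n=300$ with 60 independent LD blocks over 300 replicates. The acceptance
script runs one three-cohort study of pooled $n\approx3000$ plus one
family cohort of $n=2000$.

## Known limitations

- Variant matching is by id only; no positional matching or liftover.
- The dosage-TSV dialect carries no alleles, so harmonization requires VCF
  input (or ids whose orientation is already aligned).
- One random effect only; no GxE variance, no multi-trait mixed models.
- The linear probability model for binary outcomes mirrors the analysis
  convention it implements; its betas are not odds ratios.
- `I2` is reported on [0, 100] with small-$k$ caveats ($k=3$ cohorts makes
  heterogeneity estimates very noisy).
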
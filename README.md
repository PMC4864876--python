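# polycog

Shared genetic aetiology between a common disease and cognitive ability,
analysed end-to-end: **clump-and-threshold polygenic risk scores** from GWAS
summary statistics, **covariate- and kinship-adjusted association** with
derived cognitive phenotypes, and **fixed-effects inverse-variance
meta-analysis** across cohorts — together with a synthetic-cohort generator
that makes every stage testable against known truth.

The package is written for statistical geneticists and epidemiologists who
want a reproducible, fully tested implementation of the classic polygenic
risk-profiling design: an external case/control GWAS provides per-SNP log
odds ratios; target cohorts (including family cohorts with pedigree
structure) provide genotypes and cognitive test batteries; the question is
whether genetic liability to disease predicts cognitive performance in
disease-free population samples.

## The model

**Score.** For p-value thresholds $t \in \{0.01, 0.05, 0.1, 0.5, 1\}$, SNPs
with training-GWAS $P \le t$ are LD-pruned greedily in ascending-$P$ order
(keep a SNP iff $r^2 \le 0.25$ with every kept SNP within a ±200-SNP
window), and each individual's score is the weighted allele-dose sum

$$\mathrm{PRS}_i = \sum_j d_{ij}\,\log \mathrm{OR}_j ,$$

with missing doses imputed as $2p_j$. Effect alleles are harmonized to the
panel's counted (ALT) alleles, with sign flips on allele swaps and
strand-ambiguous A/T, C/G SNPs dropped by default.

**Association.** Unrelated cohorts: OLS of the (z-scored) phenotype on the
(z-scored) score with age, sex and the top principal components of the
standardized genotype matrix as covariates; a 0/1 disease-history outcome is
analysed by the same linear probability model. Family cohorts: the
univariate linear mixed model

$$y = X\beta + g + e,\qquad \mathrm{Var}(y) = \sigma_g^2 A + \sigma_e^2 I,$$

where $A$ is the pedigree additive-relationship matrix (tabular method).
Variance components are estimated by REML via a single eigendecomposition of
$A$ and a 1-D profile over $\lambda = \sigma_g^2/\sigma_e^2$; inference on
fixed effects is the Wald $z$ with $p = 2\Phi(-|z|)$.

**Meta-analysis.** Per trait and threshold, cohort betas are pooled with
weights $w_i = 1/\mathrm{se}_i^2$; heterogeneity is quantified by Cochran's
$Q$ and $I^2 = \max(0, 100\,(Q-\mathrm{df})/Q)$. A DerSimonian–Laird
random-effects variant is available as a toggle.

**Simulator.** Block-exchangeable latent-Gaussian haplotypes give LD
structure; nuclear families arise by block-level Mendelian transmission; a
liability-threshold disease (prevalence $K$, liability heritability $h^2$)
is genetically correlated at $r_g$ with a polygenic cognitive factor that
drives a small test battery with age, sex and family-environment effects;
a training GWAS is emulated by adding calibrated Gaussian noise to the true
effects on the log-odds scale.

## Worked example

Three simulated cohorts — one with 250 nuclear families analysed by the
kinship mixed model, two of unrelated individuals analysed by OLS — with a
true genetic correlation $r_g = -0.2$ between disease liability and
cognition:

```python
from dataclasses import replace
from polycog import RunConfig, CohortSpec, SimulationConfig, run_pipeline

family = SimulationConfig(n_founder_couples=250, offspring_per_couple=2, r_g=-0.2)
unrelated = replace(family, n_founder_couples=500, offspring_per_couple=0)
config = RunConfig(
    cohorts=[
        CohortSpec("family", sim=family, use_pedigree=True, n_components=5),
        CohortSpec("city", sim=unrelated, n_components=4),
        CohortSpec("valley", sim=unrelated, n_components=4),
    ],
    thresholds=(0.01, 0.5, 1.0),
    traits=("g_fluid", "CVD"),
    seed=7,
)
result = run_pipeline(config)
print(result.meta.round(4).to_string(index=False))
```

prints

```
  trait  threshold  k    beta     se       z   p      Q    Q_p      I2
    CVD       0.01  3  0.1877 0.0075 25.1487 0.0 3.5951 0.1657 44.3690
    CVD       0.50  3  0.1844 0.0075 24.6919 0.0 2.5088 0.2852 20.2812
    CVD       1.00  3  0.1840 0.0075 24.6087 0.0 2.4285 0.2969 17.6444
g_fluid       0.01  3 -0.0764 0.0181 -4.2316 0.0 1.3178 0.5174  0.0000
g_fluid       0.50  3 -0.0856 0.0180 -4.7542 0.0 1.2741 0.5288  0.0000
g_fluid       1.00  3 -0.0818 0.0180 -4.5409 0.0 1.2070 0.5469  0.0000
```

Reading the output: the disease score predicts disease history strongly and
positively at every threshold (`beta` is a standardized coefficient;
`z`/`p` are Wald statistics), while the fluid-ability composite shows the
induced negative association (β ≈ −0.08 here, because the simulated $r_g$
is modest and the scores are noisy proxies for genetic liability). `Q`,
`Q_p` and `I2` summarise between-cohort heterogeneity; none is significant
in this run.

A command-line interface mirrors the library: `polycog demo`, `polycog
simulate`, `polycog score`, `polycog assoc`, `polycog meta`, and `polycog
run --config run.yaml --seed 7 --out results/` for config-driven runs on
files (VCF or dosage TSV genotypes, pedigree/phenotype TSVs, summary-stats
TSV).

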
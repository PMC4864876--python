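"""Synthetic cohorts with known pleiotropy.

Every downstream stage of the pipeline is testable against ground truth
generated here:

* **LD-blocked genotypes** — haplotypes are drawn by a block-exchangeable
  latent-Gaussian threshold construction: within a block, latent normals
  share a common factor with weight ``sqrt(within_block_rho)`` and are
  thresholded at the block allele frequency, so allelic correlation within a
  block is governed by ``within_block_rho`` and blocks are independent.
* **Nuclear families** — founders receive reference haplotype pairs; each
  offspring inherits, per block, one whole block-haplotype from each parent
  (block-level Mendelian transmission, no within-block recombination).
* **Liability-threshold disease** — a standard-normal liability with genetic
  variance ``h2_liability``; disease status is liability above the
  ``1 - prevalence_K`` quantile.
* **Pleiotropy** — the cognitive genetic value is
  ``r_g * (standardized disease genetic value) + sqrt(1 - r_g^2) * g2``
  with ``g2`` an independent polygenic value on disjoint variants, so both
  components are transmitted through genotypes.
* **Training GWAS** — per-variant observed log odds ratios are the true
  liability effects mapped to the log-odds scale by the fixed constant
  ``c = phi(t) / (K (1 - K))`` with ``t = Phi^{-1}(1 - K)`` (the derivative
  of the liability-to-probability map over the log-odds derivative), plus
  Gaussian noise with ``SE = 1 / sqrt(gwas_n * 2 p (1 - p) * K (1 - K))``.

Identical configurations (including the seed) give bit-identical outputs;
all randomness flows through ``numpy.random.default_rng`` seeded with
``(seed, stage_tag)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .genopanel import GenotypePanel
from .sumstats import SummaryStats

__all__ = [
    "SimulationConfig",
    "HaplotypePanel",
    "TrueEffects",
    "make_reference_haplotypes",
    "make_cohort",
    "simulate_cad_architecture",
    "simulate_cog_architecture",
    "simulate_gwas_sumstats",
    "simulate_phenotypes",
    "liability_to_logodds_scale",
]

# stage tags keep per-stage random streams independent under one seed
_STAGE_REF, _STAGE_COHORT, _STAGE_ARCH, _STAGE_GWAS, _STAGE_PHENO, _STAGE_COG = range(1, 7)

TEST_LOADINGS = {
    "logical_memory": 0.85,
    "verbal_fluency": 0.75,
    "digit_symbol": 0.80,
    "vocabulary": 0.70,
}

_UNAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                      ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort and its training GWAS.

    Defaults describe a family cohort of 250 nuclear families (1000 people)
    genotyped at 750 SNPs in 30 LD blocks, a disease with 25% lifetime
    prevalence and liability heritability 0.4 concentrated in 150 causal
    variants, a cognitive trait with heritability 0.5 genetically correlated
    at r_g with disease liability, and a training GWAS of about 87 000
    case/control samples (the scale of the large coronary-artery-disease
    consortium analyses).
    """

    n_blocks: int = 30
    snps_per_block: int = 25
    within_block_rho: float = 0.4
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_founder_couples: int = 250
    offspring_per_couple: int = 2
    n_causal: int = 150
    h2_liability: float = 0.4
    prevalence_K: float = 0.25
    r_g: float = -0.2
    h2_cog: float = 0.5
    beta_age: float = -0.3
    beta_sex: float = 0.1
    sigma_family: float = 0.2
    gwas_n: int = 86995
    age_low: float = 25.0
    age_high: float = 90.0
    frac_ambiguous: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise ConfigError("n_blocks and snps_per_block must be >= 1")
        if not (0.0 <= self.within_block_rho <= 1.0):
            raise ConfigError("within_block_rho must lie in [0,1]")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError(
                f"invalid MAF bounds ({self.maf_low}, {self.maf_high}); "
                "need 0 < low <= high <= 0.5"
            )
        if self.n_causal > self.n_blocks * self.snps_per_block:
            raise ConfigError("n_causal exceeds the number of variants")
        for name in ("h2_liability", "h2_cog"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if not (0.0 < self.prevalence_K < 1.0):
            raise ConfigError("prevalence_K must lie in (0,1)")
        if not (-1.0 <= self.r_g <= 1.0):
            raise ConfigError("r_g must lie in [-1,1]")
        if not (0.0 <= self.sigma_family <= 1.0):
            raise ConfigError("sigma_family must lie in [0,1] (share of unit "
                              "environmental SD)")
        if self.gwas_n <= 0:
            raise ConfigError("gwas_n must be positive")
        if self.n_founder_couples < 0 or self.offspring_per_couple < 0:
            raise ConfigError("family counts must be nonnegative")
        if self.age_low >= self.age_high:
            raise ConfigError("age_low must be below age_high")
        if not (0.0 <= self.frac_ambiguous <= 1.0):
            raise ConfigError("frac_ambiguous must lie in [0,1]")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def n_samples(self) -> int:
        return self.n_founder_couples * (2 + self.offspring_per_couple)


@dataclass
class HaplotypePanel:
    """Reference haplotypes: 2 x samples rows over blocked variants."""

    haplotypes: np.ndarray  # (n_haplotypes, n_variants) of 0/1
    variants: pd.DataFrame  # id, block, ref, alt, maf

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class TrueEffects:
    """Ground-truth per-standardized-allele liability effects.

    ``table`` columns: ``variant_id``, ``beta`` (0 for non-causal),
    ``causal`` (bool).  ``h2_target`` is the variance the weighted sum of
    standardized genotypes was scaled to on the architecture panel.
    """

    table: pd.DataFrame
    h2_target: float

    def __post_init__(self) -> None:
        noncausal = self.table.loc[~self.table["causal"], "beta"]
        if (noncausal != 0).any():
            raise ConfigError("non-causal variants must have effect exactly 0")

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy()


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _draw_haplotypes(
    rng: np.random.Generator, n_hap: int, cfg: SimulationConfig,
    thresholds: np.ndarray,
) -> np.ndarray:
    """Latent-Gaussian threshold haplotypes, block-exchangeable correlation."""
    rho = cfg.within_block_rho
    m = cfg.n_variants
    haps = np.empty((n_hap, m), dtype=np.uint8)
    for b in range(cfg.n_blocks):
        sl = slice(b * cfg.snps_per_block, (b + 1) * cfg.snps_per_block)
        shared = rng.standard_normal((n_hap, 1))
        noise = rng.standard_normal((n_hap, cfg.snps_per_block))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        haps[:, sl] = (z < thresholds[sl]).astype(np.uint8)
    return haps


def make_reference_haplotypes(
    cfg: SimulationConfig, n_samples: Optional[int] = None, draw_tag: int = 0
) -> HaplotypePanel:
    """Reference haplotype pool (2 haplotypes per sample).

    The allele frequency is drawn once per block and shared by the block's
    variants, so perfect within-block correlation (rho = 1) collapses the
    block to identical columns.  Allele pairs are assigned per variant; a
    ``frac_ambiguous`` fraction gets strand-ambiguous A/T or C/G pairs so
    harmonization policies are exercised.

    The variant definitions (frequencies, alleles) depend only on the seed,
    while the haplotype draw also depends on ``draw_tag``: pools with
    different tags are independent draws from the same population model, so
    multiple cohorts can be sampled without sharing haplotypes.
    """
    if n_samples is None:
        n_samples = max(2 * cfg.n_founder_couples, 100)
    rng = _rng(cfg, _STAGE_REF)
    m = cfg.n_variants
    block_maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_blocks)
    maf = np.repeat(block_maf, cfg.snps_per_block)
    thresholds = stats.norm.ppf(maf)

    pair_pool = np.array(_UNAMBIGUOUS_PAIRS)
    amb_pool = np.array(_AMBIGUOUS_PAIRS)
    use_amb = rng.random(m) < cfg.frac_ambiguous
    pairs = pair_pool[rng.integers(len(pair_pool), size=m)]
    pairs[use_amb] = amb_pool[rng.integers(len(amb_pool), size=int(use_amb.sum()))]

    variants = pd.DataFrame({
        "id": [f"rs{k + 1:06d}" for k in range(m)],
        "block": np.repeat(np.arange(cfg.n_blocks), cfg.snps_per_block),
        "ref": pairs[:, 0],
        "alt": pairs[:, 1],
        "maf": maf,
    })
    hap_rng = np.random.default_rng([cfg.seed, _STAGE_REF, 1 + draw_tag])
    haps = _draw_haplotypes(hap_rng, 2 * n_samples, cfg, thresholds)
    return HaplotypePanel(haps, variants)


def make_cohort(
    ref: HaplotypePanel,
    cfg: SimulationConfig,
    id_prefix: str = "s",
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Founders plus block-Mendelian offspring, with a pedigree table.

    Founders are random haplotype pairs from the reference pool; each
    offspring receives, independently per block, one whole block-haplotype
    from each parent.  The pedigree has columns ``id``, ``father``,
    ``mother``, ``sex`` (``0`` = founder parent code) plus a ``family``
    column grouping each couple with its children.
    """
    if ref.n_haplotypes == 0:
        raise ConfigError("reference haplotype panel is empty")
    if cfg.offspring_per_couple > 0 and cfg.n_founder_couples == 0:
        raise ConfigError("offspring requested but no founder couples")
    rng = _rng(cfg, _STAGE_COHORT)
    m = ref.n_variants
    n_founders = 2 * cfg.n_founder_couples
    n_off = cfg.n_founder_couples * cfg.offspring_per_couple
    n_total = n_founders + n_off

    need = 2 * n_founders
    if need <= ref.n_haplotypes:
        hap_idx = rng.choice(ref.n_haplotypes, size=need, replace=False)
    else:
        hap_idx = rng.integers(ref.n_haplotypes, size=need)
    founder_haps = ref.haplotypes[hap_idx].reshape(n_founders, 2, m)

    ids = [f"{id_prefix}{k + 1:05d}" for k in range(n_total)]
    father, mother, sex, family = [], [], [], []
    hap_store = np.empty((n_total, 2, m), dtype=np.uint8)
    hap_store[:n_founders] = founder_haps

    block_of = ref.variants["block"].to_numpy()
    n_blocks = int(block_of.max()) + 1 if m else 0
    for c in range(cfg.n_founder_couples):
        for w in range(2):
            father.append("0")
            mother.append("0")
            sex.append("M" if w == 0 else "F")
            family.append(f"fam{c + 1:04d}")

    k = n_founders
    for c in range(cfg.n_founder_couples):
        dad, mum = 2 * c, 2 * c + 1
        for _ in range(cfg.offspring_per_couple):
            for parent_slot, parent in ((0, dad), (1, mum)):
                choice = rng.integers(2, size=n_blocks)
                hap_store[k, parent_slot] = hap_store[parent, choice[block_of], np.arange(m)]
            father.append(ids[dad])
            mother.append(ids[mum])
            sex.append("M" if rng.random() < 0.5 else "F")
            family.append(f"fam{c + 1:04d}")
            k += 1

    dosages = hap_store.sum(axis=1).astype(float)
    panel = GenotypePanel(ids, ref.variants[["id", "ref", "alt"]].copy(), dosages)
    pedigree = pd.DataFrame(
        {"id": ids, "father": father, "mother": mother, "sex": sex, "family": family}
    )
    return panel, pedigree


def _standardized_dosages(panel: GenotypePanel, cols: np.ndarray) -> np.ndarray:
    D = panel.dosages[:, cols]
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic columns contribute nothing
    return (D - mu) / sd


def simulate_cad_architecture(panel: GenotypePanel, cfg: SimulationConfig) -> TrueEffects:
    """Draw the disease architecture: ``n_causal`` variants with zero-mean
    effects, rescaled so the genetic liability variance on *panel* equals
    ``h2_liability`` exactly."""
    m = panel.n_variants
    if cfg.n_causal > m:
        raise ConfigError(f"n_causal={cfg.n_causal} exceeds panel size {m}")
    rng = _rng(cfg, _STAGE_ARCH)
    causal = np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
    betas = np.zeros(m)
    if cfg.h2_liability > 0 and cfg.n_causal > 0:
        raw = rng.standard_normal(cfg.n_causal)
        g = _standardized_dosages(panel, causal) @ raw
        var = g.var()
        if var > 0:
            betas[causal] = raw * np.sqrt(cfg.h2_liability / var)
    table = pd.DataFrame({
        "variant_id": panel.variants["id"],
        "beta": betas,
        "causal": np.isin(np.arange(m), causal),
    })
    return TrueEffects(table, cfg.h2_liability)


def simulate_cog_architecture(
    panel: GenotypePanel, cad_effects: TrueEffects, cfg: SimulationConfig
) -> TrueEffects:
    """Polygenic architecture for the cognition-specific genetic component.

    Effects are drawn on variants disjoint from the disease-causal set and
    then orthogonalized against the disease genetic value on *panel*:
    because disease- and cognition-causal variants can share LD blocks, a
    raw draw would leak genetic correlation even at ``r_g = 0``.  The
    returned effect vector therefore carries a small counterweight on the
    disease-causal variants; its genetic value has variance 1 and
    correlation ~0 with the disease genetic value, so ``r_g`` alone
    controls pleiotropy.
    """
    rng = _rng(cfg, _STAGE_COG)
    m = panel.n_variants
    pool = np.flatnonzero(~cad_effects.table["causal"].to_numpy())
    if pool.size == 0:
        raise ConfigError("no non-causal variants left for the cognition architecture")
    k = min(cfg.n_causal, pool.size)
    causal = np.sort(rng.choice(pool, size=k, replace=False))
    raw = rng.standard_normal(k)
    betas = np.zeros(m)
    betas[causal] = raw
    all_cols = np.arange(m)
    Xstd = _standardized_dosages(panel, all_cols)
    g2 = Xstd @ betas
    g_cad = Xstd @ cad_effects.betas
    var_cad = g_cad.var()
    if var_cad > 0:
        gamma = np.cov(g2, g_cad, ddof=0)[0, 1] / var_cad
        betas = betas - gamma * cad_effects.betas
        g2 = g2 - gamma * g_cad
    var = g2.var()
    if var > 0:
        betas = betas / np.sqrt(var)
    table = pd.DataFrame({
        "variant_id": panel.variants["id"],
        "beta": betas,
        "causal": betas != 0.0,
    })
    return TrueEffects(table, 1.0)


def liability_to_logodds_scale(K: float) -> float:
    """Fixed proportionality constant mapping liability effects to log odds
    ratios: ``phi(t) / (K(1-K))`` with ``t = Phi^{-1}(1-K)``."""
    t = stats.norm.ppf(1.0 - K)
    return float(stats.norm.pdf(t) / (K * (1.0 - K)))


def gwas_standard_error(freq, gwas_n: int, K: float) -> np.ndarray:
    """Per-variant log-OR standard error,
    ``1 / sqrt(gwas_n * 2 p (1-p) * K (1-K))``."""
    p = np.clip(np.asarray(freq, dtype=float), 1e-4, 1 - 1e-4)
    return 1.0 / np.sqrt(gwas_n * 2.0 * p * (1.0 - p) * K * (1.0 - K))


def simulate_gwas_sumstats(
    effects: TrueEffects,
    panel_frequencies: np.ndarray,
    cfg: SimulationConfig,
    variants: pd.DataFrame | None = None,
) -> SummaryStats:
    """Noisy training-GWAS summary statistics for every variant.

    Observed log OR = c * beta + N(0, SE) with
    ``SE = 1/sqrt(gwas_n * 2p(1-p) * K(1-K))``; the two-sided normal p-value
    follows.  Half the rows (deterministically chosen) are emitted with
    effect/other alleles swapped (log OR negated) so harmonization is
    exercised; alleles always stay consistent with the panel metadata.
    """
    K = cfg.prevalence_K
    p = np.clip(np.asarray(panel_frequencies, dtype=float), 1e-4, 1 - 1e-4)
    se = gwas_standard_error(p, cfg.gwas_n, K)
    c = liability_to_logodds_scale(K)
    rng = _rng(cfg, _STAGE_GWAS)
    log_or = c * effects.betas + rng.normal(0.0, se)
    zval = log_or / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(zval)), 1e-300, 1.0)

    if variants is None:
        variants = pd.DataFrame({
            "id": effects.table["variant_id"],
            "ref": "A", "alt": "G",
        })
    swap = rng.random(len(p)) < 0.5
    a1 = np.where(swap, variants["ref"], variants["alt"])
    a2 = np.where(swap, variants["alt"], variants["ref"])
    out_logor = np.where(swap, -log_or, log_or)
    eaf = np.where(swap, 1.0 - p, p)
    table = pd.DataFrame({
        "snp": effects.table["variant_id"].to_numpy(),
        "a1": a1, "a2": a2,
        "log_or": out_logor, "p": pval, "eaf": eaf,
    })
    return SummaryStats(table)


def _family_groups(pedigree: pd.DataFrame) -> pd.Series:
    if "family" in pedigree.columns:
        return pedigree["family"]
    # union-find over parent-child links
    ids = [str(s) for s in pedigree["id"]]
    parent = {s: s for s in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for rec in pedigree.itertuples(index=False):
        for pcol in (rec.father, rec.mother):
            pstr = str(pcol)
            if pstr in parent and not pd.isna(pcol) and pstr != "0":
                ra, rb = find(str(rec.id)), find(pstr)
                if ra != rb:
                    parent[ra] = rb
    return pd.Series([find(s) for s in ids], index=pedigree.index)


def simulate_phenotypes(
    panel: GenotypePanel,
    pedigree: pd.DataFrame,
    effects: TrueEffects,
    cfg: SimulationConfig,
    cog_effects: TrueEffects | None = None,
) -> pd.DataFrame:
    """Cognitive test battery, disease status, age and sex for one cohort.

    Disease: liability = genetic value + Gaussian residual (total variance
    1); status is liability above the ``1 - prevalence_K`` quantile.
    Cognition: the latent factor mixes the standardized disease genetic
    value (weight ``r_g``) with an independent polygenic value, is scaled to
    heritability ``h2_cog``, and receives family-shared environmental noise
    (SD ``sigma_family`` of the unit environmental SD) plus unique noise.
    Each named test loads on the factor and additionally carries age and sex
    effects (per-SD units).  Returns a table with one row per sample:
    tests, ``CVD``, ``age``, ``sex``, ``family``.
    """
    ids = [str(s) for s in panel.samples]
    if [str(s) for s in pedigree["id"]] != ids:
        raise ConfigError("pedigree and panel samples differ or are reordered")
    if list(effects.table["variant_id"]) != list(panel.variants["id"]):
        raise ConfigError("effects and panel variants differ")
    n = panel.n_samples
    rng = _rng(cfg, _STAGE_PHENO)

    def _zs(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    all_cols = np.arange(panel.n_variants)
    g_cad = _standardized_dosages(panel, all_cols) @ effects.betas
    g_cad_std = _zs(g_cad)

    if cog_effects is None:
        cog_effects = simulate_cog_architecture(panel, effects, cfg)
    g2_std = _zs(_standardized_dosages(panel, all_cols) @ cog_effects.betas)
    r = cfg.r_g
    g_cog = r * g_cad_std + np.sqrt(1.0 - r * r) * g2_std

    liability = g_cad + rng.normal(0.0, np.sqrt(max(0.0, 1.0 - cfg.h2_liability)), n)
    cvd = (liability > stats.norm.ppf(1.0 - cfg.prevalence_K)).astype(int)

    fam = _family_groups(pedigree)
    fam_codes, fam_index = pd.factorize(fam)
    fam_noise = rng.normal(0.0, cfg.sigma_family, len(fam_index))[fam_codes]
    unique_sd = np.sqrt(max(0.0, 1.0 - cfg.sigma_family**2))
    env = fam_noise + rng.normal(0.0, unique_sd, n)
    factor = np.sqrt(cfg.h2_cog) * g_cog + np.sqrt(1.0 - cfg.h2_cog) * env

    age = rng.uniform(cfg.age_low, cfg.age_high, n)
    age_sd = (cfg.age_high - cfg.age_low) / np.sqrt(12.0)
    age_z = (age - (cfg.age_low + cfg.age_high) / 2.0) / age_sd
    sex = pedigree["sex"].astype(str).to_numpy()
    sex_ind = np.where(sex == "M", 0.5, -0.5)

    out = {"sample_id": ids}
    for test, load in TEST_LOADINGS.items():
        noise = rng.normal(0.0, np.sqrt(1.0 - load**2), n)
        out[test] = (load * factor + noise
                     + cfg.beta_age * age_z + cfg.beta_sex * sex_ind)
    out["CVD"] = cvd
    out["age"] = age
    out["sex"] = sex
    out["family"] = fam.to_numpy()
    # ground truth for calibration checks; never used as analysis traits
    out["latent_liability"] = liability
    out["latent_g_cad"] = g_cad_std
    out["latent_g_cog"] = g_cog
    out["latent_factor"] = factor
    return pd.DataFrame(out)


def write_pedigree_tsv(pedigree: pd.DataFrame, path) -> None:
    """Write the 4-column pedigree dialect (id, father, mother, sex; 0 =
    founder parent code)."""
    pedigree[["id", "father", "mother", "sex"]].to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "father", "mother"):
        if col not in ped.columns:
            from .errors import FormatError

            raise FormatError(f"pedigree TSV missing column {col!r}")
    return ped
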
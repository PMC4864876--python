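"""Config-driven end-to-end runs.

A run takes one or more cohorts (simulated, or loaded from genotype /
pedigree / phenotype files), builds clump-and-threshold polygenic scores at
every requested p-value threshold, derives the fluid-ability composite,
fits covariate-adjusted association models per cohort (pedigree-REML mixed
model for family cohorts, OLS otherwise), pools cohorts by fixed-effects
inverse-variance meta-analysis, and writes tidy TSV outputs plus a
structured run log.  Results are deterministic given the seed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .assoc import kinship_from_pedigree, linear_assoc
from .errors import ConfigError, PolycogError
from .genopanel import GenotypePanel, read_genotypes, stratification_components
from .meta import fixed_effect_meta, forest_table
from .phenotypes import composite_pc1, exclude_outliers
from .prs import THRESHOLD_GRID, PolygenicScorer
from .simulate import (
    SimulationConfig,
    make_cohort,
    make_reference_haplotypes,
    read_pedigree_tsv,
    simulate_cad_architecture,
    simulate_cog_architecture,
    simulate_gwas_sumstats,
    simulate_phenotypes,
    write_pedigree_tsv,
)
from .sumstats import SummaryStats, read_sumstats

__all__ = ["CohortSpec", "RunConfig", "PipelineResult", "run_pipeline", "make_demo_dataset"]

COMPOSITE_TESTS = ("logical_memory", "verbal_fluency", "digit_symbol")
DEFAULT_TRAITS = ("g_fluid", "vocabulary", "logical_memory", "verbal_fluency",
                  "digit_symbol", "CVD")


@dataclass
class CohortSpec:
    """One cohort: either a simulation config or file paths.

    ``use_pedigree`` switches the association model to the kinship-REML
    mixed model; ``n_components`` is the number of ancestry components used
    as covariates (cohort-specific, e.g. 4 or 5).
    """

    name: str
    sim: Optional[SimulationConfig] = None
    genotypes: Optional[str] = None
    genotype_format: str = "vcf"
    pedigree: Optional[str] = None
    phenotypes: Optional[str] = None
    use_pedigree: bool = False
    n_components: int = 4

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.genotypes is None):
            raise ConfigError(
                f"cohort {self.name!r}: give exactly one of a simulation "
                "config or genotype paths"
            )
        if self.genotypes is not None and self.phenotypes is None:
            raise ConfigError(f"cohort {self.name!r}: phenotype table required")
        if self.use_pedigree and self.genotypes is not None and self.pedigree is None:
            raise ConfigError(f"cohort {self.name!r}: pedigree required for mixed model")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    cohorts: list[CohortSpec]
    thresholds: tuple = THRESHOLD_GRID
    traits: tuple = DEFAULT_TRAITS
    sumstats_path: Optional[str] = None
    exclude_cvd: bool = False
    age_band: Optional[tuple] = None  # (low, high); half-open [low, high)
    adjust_for: dict = field(default_factory=dict)  # trait -> extra covariate trait
    interaction: Optional[str] = None  # covariate name, e.g. "age"
    outlier_sd: float = 3.5
    r2_max: float = 0.25
    window: int = 200
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ConfigError("at least one cohort is required")
        for t in self.thresholds:
            if not (0.0 < t <= 1.0):
                raise ConfigError(f"threshold {t} outside (0,1]")
        if self.age_band is not None and self.age_band[0] >= self.age_band[1]:
            raise ConfigError("age band must be (low, high) with low < high")
        sims = [c for c in self.cohorts if c.sim is not None]
        if not sims and self.sumstats_path is None:
            raise ConfigError("sumstats_path required when no cohort is simulated")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = []
        for c in raw.pop("cohorts"):
            sim = c.pop("sim", None)
            if sim is not None:
                sim = SimulationConfig(**sim)
            cohorts.append(CohortSpec(sim=sim, **c))
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        if "age_band" in raw and raw["age_band"] is not None:
            raw["age_band"] = tuple(raw["age_band"])
        return cls(cohorts=cohorts, **raw)


@dataclass
class PipelineResult:
    associations: pd.DataFrame
    meta: pd.DataFrame
    snp_counts: pd.DataFrame
    forest: pd.DataFrame
    log: list[str]


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.default_rng([seed, 91, tag]).integers(2**31))


@dataclass
class _Cohort:
    spec: CohortSpec
    panel: GenotypePanel
    pedigree: Optional[pd.DataFrame]
    phenotypes: pd.DataFrame


def _materialize_cohorts(config: RunConfig, log: list[str]) -> tuple[list[_Cohort], SummaryStats]:
    """Simulate or load every cohort, and obtain summary statistics.

    Simulated cohorts share one reference haplotype pool and one disease /
    cognition architecture (drawn under the run seed), like cohorts sampled
    from a common population; cohort-level randomness uses per-cohort child
    seeds.
    """
    sim_specs = [c for c in config.cohorts if c.sim is not None]
    shared = None
    if sim_specs:
        master = replace(sim_specs[0].sim, seed=_child_seed(config.seed, 0))
        # a large founders-only panel (independent haplotype draw) pins down
        # architecture scaling and the disease/cognition orthogonalization
        arch_cfg = replace(master, offspring_per_couple=0,
                           n_founder_couples=max(master.n_founder_couples, 1250))
        arch_ref = make_reference_haplotypes(
            master, n_samples=2 * arch_cfg.n_founder_couples, draw_tag=1000
        )
        arch_panel, _ = make_cohort(arch_ref, arch_cfg, "arch")
        effects = simulate_cad_architecture(arch_panel, master)
        cog_effects = simulate_cog_architecture(arch_panel, effects, master)
        sumstats = simulate_gwas_sumstats(
            effects, arch_panel.allele_frequencies(), master,
            variants=arch_panel.variants,
        )
        shared = (master, effects, cog_effects)
        log.append(f"simulated training GWAS over {len(sumstats)} variants "
                   f"(gwas_n={master.gwas_n}, seed={master.seed})")
    if config.sumstats_path is not None:
        sumstats = read_sumstats(config.sumstats_path)
        log.append(f"read sumstats {config.sumstats_path}: {len(sumstats)} records, "
                   f"{len(sumstats.rejects)} rejected rows")

    cohorts = []
    for i, spec in enumerate(config.cohorts):
        if spec.sim is not None:
            master, effects, cog_effects = shared
            cfg_i = replace(spec.sim, seed=_child_seed(config.seed, i + 1))
            # each cohort is an independent haplotype draw from the shared
            # population model (same variant definitions, fresh pool)
            ref_i = make_reference_haplotypes(
                master, n_samples=2 * cfg_i.n_founder_couples, draw_tag=i + 1
            )
            panel, ped = make_cohort(ref_i, cfg_i, id_prefix=f"{spec.name}_s")
            phenos = simulate_phenotypes(panel, ped, effects, cfg_i, cog_effects=cog_effects)
            log.append(f"cohort {spec.name}: simulated n={panel.n_samples}, "
                       f"m={panel.n_variants}, seed={cfg_i.seed}")
        else:
            panel = read_genotypes(spec.genotypes, spec.genotype_format, log)
            phenos = pd.read_csv(spec.phenotypes, sep="\t", dtype={"sample_id": str})
            ped = read_pedigree_tsv(spec.pedigree) if spec.pedigree else None
            if list(phenos["sample_id"]) != list(panel.samples):
                raise ConfigError(
                    f"cohort {spec.name}: phenotype rows do not match panel samples"
                )
            log.append(f"cohort {spec.name}: loaded n={panel.n_samples}, "
                       f"m={panel.n_variants} [{panel.fingerprint()}]")
        cohorts.append(_Cohort(spec, panel, ped, phenos))
    return cohorts, sumstats


def _derive_traits(cohort: _Cohort, config: RunConfig, log: list[str]) -> pd.DataFrame:
    """Composite derivation and single-pass outlier exclusion per trait."""
    phenos = cohort.phenotypes.copy()
    tests = [c for c in COMPOSITE_TESTS if c in phenos.columns]
    if "g_fluid" in config.traits or "g_fluid" in config.adjust_for.values():
        if len(tests) < 2:
            raise ConfigError("need >= 2 component tests for the fluid composite")
        comp, _, var_expl = composite_pc1(phenos[tests])
        phenos["g_fluid"] = comp.to_numpy()
        log.append(f"cohort {cohort.spec.name}: fluid composite over {tests} "
                   f"(variance explained {var_expl:.3f})")
    for trait in config.traits:
        if trait == "CVD" or trait not in phenos.columns:
            continue
        keep = exclude_outliers(phenos[trait].to_numpy(dtype=float), config.outlier_sd)
        n_exc = int((~keep).sum())
        if n_exc:
            phenos.loc[~keep, trait] = np.nan
        log.append(f"cohort {cohort.spec.name}: {trait}: {n_exc} outliers "
                   f"beyond +/-{config.outlier_sd} SD excluded")
    return phenos


def _analyze_cohort(
    cohort: _Cohort,
    phenos: pd.DataFrame,
    sumstats: SummaryStats,
    config: RunConfig,
    log: list[str],
) -> tuple[list[dict], list[dict]]:
    spec = cohort.spec
    comps = stratification_components(cohort.panel, spec.n_components)
    covars = pd.DataFrame(
        comps, columns=[f"comp{j + 1}" for j in range(spec.n_components)]
    )
    covars["age"] = phenos["age"].to_numpy(dtype=float)
    covars["sex"] = (phenos["sex"].astype(str) == "M").astype(float).to_numpy()

    kinship = None
    if spec.use_pedigree:
        if cohort.pedigree is None:
            raise ConfigError(f"cohort {spec.name}: pedigree missing")
        kinship = kinship_from_pedigree(cohort.pedigree)

    subset = np.ones(len(phenos), dtype=bool)
    if config.exclude_cvd:
        subset &= phenos["CVD"].to_numpy() == 0
        log.append(f"cohort {spec.name}: excluded "
                   f"{int((phenos['CVD'] == 1).sum())} CVD cases")
    if config.age_band is not None:
        lo, hi = config.age_band
        age = phenos["age"].to_numpy(dtype=float)
        subset &= (age >= lo) & (age < hi)
        log.append(f"cohort {spec.name}: age band [{lo},{hi}) keeps {int(subset.sum())}")

    assoc_rows, count_rows = [], []
    for thr in config.thresholds:
        scorer = PolygenicScorer(
            sumstats=sumstats, p_threshold=thr,
            r2_max=config.r2_max, window=config.window,
        ).fit(cohort.panel)
        excl = scorer.weights_.exclusion_counts
        count_rows.append({
            "cohort": spec.name, "threshold": thr,
            "n_thresholded": len(scorer.weights_) + sum(excl.values()),
            "n_harmonized": len(scorer.weights_),
            "n_after_prune": scorer.n_variants_,
            **{f"excluded_{k}": v for k, v in excl.items()},
        })
        log.append(f"cohort {spec.name} thr={thr}: {len(scorer.weights_)} harmonized "
                   f"({excl}), {scorer.n_variants_} kept after LD pruning")
        score = scorer.transform(cohort.panel).ravel()
        for trait in config.traits:
            if trait == "CVD" and config.exclude_cvd:
                continue
            if trait not in phenos.columns:
                raise ConfigError(f"trait {trait!r} not present in cohort {spec.name}")
            y = phenos[trait].to_numpy(dtype=float).copy()
            y[~subset] = np.nan
            cv = covars.copy()
            extra = config.adjust_for.get(trait)
            if extra is not None:
                cv[f"adj_{extra}"] = phenos[extra].to_numpy(dtype=float)
            res = linear_assoc(
                y, score, cv, standardize=True,
                interaction=config.interaction,
                kinship=kinship, sample_ids=list(cohort.panel.samples),
                trait=trait, threshold=thr,
            )
            row = {"cohort": spec.name, **res.as_dict(),
                   "model": "reml-lmm" if kinship is not None else "ols",
                   "coefficient": res.coefficient}
            assoc_rows.append(row)
    return assoc_rows, count_rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a full run; write TSV outputs when ``config.out_dir`` is set.

    Any stage failure aborts with a stage-named message and removes partial
    outputs.
    """
    log: list[str] = [f"run seed={config.seed}; thresholds={list(config.thresholds)}; "
                      f"traits={list(config.traits)}"]
    out_dir = Path(config.out_dir) if config.out_dir else None
    created = False
    try:
        stage = "cohort assembly"
        cohorts, sumstats = _materialize_cohorts(config, log)
        stage = "trait derivation"
        derived = [_derive_traits(c, config, log) for c in cohorts]
        stage = "association"
        assoc_rows, count_rows = [], []
        for cohort, phenos in zip(cohorts, derived):
            a, c = _analyze_cohort(cohort, phenos, sumstats, config, log)
            assoc_rows.extend(a)
            count_rows.extend(c)
        assoc = pd.DataFrame(assoc_rows)
        stage = "meta-analysis"
        meta_rows, forest_rows = [], []
        for (trait, thr), grp in assoc.groupby(["trait", "threshold"], sort=True):
            est = list(zip(grp["beta"], grp["se"]))
            mr = fixed_effect_meta(est)
            meta_rows.append({"trait": trait, "threshold": thr, **mr.as_dict()})
            ft = forest_table(grp["cohort"].tolist(), est)
            ft.insert(0, "threshold", thr)
            ft.insert(0, "trait", trait)
            forest_rows.append(ft)
        meta = pd.DataFrame(meta_rows)
        forest = pd.concat(forest_rows, ignore_index=True) if forest_rows else pd.DataFrame()
        snp_counts = pd.DataFrame(count_rows)

        if out_dir is not None:
            stage = "output"
            created = not out_dir.exists()
            out_dir.mkdir(parents=True, exist_ok=True)
            assoc.to_csv(out_dir / "associations.tsv", sep="\t", index=False,
                         float_format="%.10g")
            meta.to_csv(out_dir / "meta.tsv", sep="\t", index=False,
                        float_format="%.10g")
            forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False,
                          float_format="%.10g")
            snp_counts.to_csv(out_dir / "snp_counts.tsv", sep="\t", index=False)
            (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
        return PipelineResult(assoc, meta, snp_counts, forest, log)
    except PolycogError as exc:
        if out_dir is not None and out_dir.exists() and created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc


def make_demo_dataset(out_dir, seed: int = 0) -> dict:
    """Write a small self-contained three-cohort dataset (r_g = -0.2).

    One family cohort (VCF + dosage TSV + pedigree) and two unrelated
    cohorts, with phenotype tables and a shared training-GWAS summary
    statistics TSV; every file parses back through the package readers.
    Returns the path map.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ConfigError(f"cannot write to {out}: {exc}") from exc

    base = SimulationConfig(
        n_blocks=12, snps_per_block=20, n_founder_couples=80,
        offspring_per_couple=2, n_causal=48, r_g=-0.2,
        seed=_child_seed(seed, 0),
    )
    arch_ref = make_reference_haplotypes(base, n_samples=2000, draw_tag=1000)
    arch_panel, _ = make_cohort(
        arch_ref, replace(base, offspring_per_couple=0, n_founder_couples=1000), "arch"
    )
    effects = simulate_cad_architecture(arch_panel, base)
    cog_effects = simulate_cog_architecture(arch_panel, effects, base)
    sumstats = simulate_gwas_sumstats(
        effects, arch_panel.allele_frequencies(), base, variants=arch_panel.variants
    )
    sumstats.to_tsv(out / "sumstats.tsv")

    paths = {"sumstats": str(out / "sumstats.tsv")}
    specs = [
        ("family", replace(base, seed=_child_seed(seed, 1))),
        ("urban", replace(base, n_founder_couples=120, offspring_per_couple=0,
                          seed=_child_seed(seed, 2))),
        ("rural", replace(base, n_founder_couples=120, offspring_per_couple=0,
                          seed=_child_seed(seed, 3))),
    ]
    for tag, (name, cfg) in enumerate(specs, start=1):
        ref = make_reference_haplotypes(
            base, n_samples=2 * cfg.n_founder_couples, draw_tag=tag
        )
        panel, ped = make_cohort(ref, cfg, id_prefix=f"{name}_s")
        phenos = simulate_phenotypes(panel, ped, effects, cfg, cog_effects=cog_effects)
        panel.to_vcf(out / f"{name}.vcf")
        panel.to_dosage_tsv(out / f"{name}.dosage.tsv")
        write_pedigree_tsv(ped, out / f"{name}.ped.tsv")
        phenos.to_csv(out / f"{name}.pheno.tsv", sep="\t", index=False,
                      float_format="%.6g")
        paths[name] = str(out)
    return paths
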
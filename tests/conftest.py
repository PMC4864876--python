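import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polycog.genopanel import GenotypePanel
from polycog.simulate import (
    SimulationConfig,
    make_cohort,
    make_reference_haplotypes,
    simulate_cad_architecture,
    simulate_cog_architecture,
    simulate_gwas_sumstats,
    simulate_phenotypes,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_panel(dosages, ids=None, ref="A", alt="G") -> GenotypePanel:
    """Tiny panel from an explicit dosage matrix (rows = samples)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if ids is None:
        ids = [f"v{j + 1}" for j in range(m)]
    variants = pd.DataFrame({"id": ids, "ref": [ref] * m, "alt": [alt] * m})
    return GenotypePanel([f"s{i + 1}" for i in range(n)], variants, dosages)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_blocks=8, snps_per_block=15, n_founder_couples=120,
        offspring_per_couple=2, n_causal=40, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    ref = make_reference_haplotypes(small_cfg)
    panel, ped = make_cohort(ref, small_cfg)
    return panel, ped


@pytest.fixture(scope="session")
def small_world(small_cfg, small_cohort):
    """Cohort plus architecture, summary statistics and phenotypes."""
    panel, ped = small_cohort
    effects = simulate_cad_architecture(panel, small_cfg)
    cog = simulate_cog_architecture(panel, effects, small_cfg)
    sumstats = simulate_gwas_sumstats(
        effects, panel.allele_frequencies(), small_cfg, variants=panel.variants
    )
    phenos = simulate_phenotypes(panel, ped, effects, small_cfg, cog_effects=cog)
    return {
        "cfg": small_cfg, "panel": panel, "pedigree": ped,
        "effects": effects, "cog_effects": cog,
        "sumstats": sumstats, "phenotypes": phenos,
    }
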
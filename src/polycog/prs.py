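"""Clump-and-threshold polygenic risk scores.

A score at one p-value threshold is the cumulative sum over retained SNPs of
allele dose times the training-GWAS log odds ratio.  Retention is greedy and
p-informed ("clumping"): variants are visited in ascending training p-value
and kept only if their dosage r-squared with every already-kept variant
within a +/-``window``-SNP neighbourhood stays at or below ``r2_max``
(defaults r2_max=0.25, window=200).  A plain position-order prune is
available as a toggle.  Missing doses contribute 2 x allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DegenerateDataError
from .genopanel import GenotypePanel
from .sumstats import HarmonizedWeights, SummaryStats, harmonize, threshold_select

__all__ = [
    "PruneConfig",
    "PRSProfile",
    "ld_r2",
    "prune_ld",
    "compute_prs",
    "standardize_scores",
    "PolygenicScorer",
]

THRESHOLD_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class PruneConfig:
    """LD pruning parameters.

    r2_max : maximum admissible dosage r-squared between kept variants.
    window : neighbourhood half-width in SNPs (panel order).
    p_informed : visit variants by ascending p (clumping) rather than
        panel order.
    """

    r2_max: float = 0.25
    window: int = 200
    p_informed: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_max <= 1.0):
            raise ConfigError(f"r2_max must be in [0,1], got {self.r2_max}")
        if self.window < 1:
            raise ConfigError(f"window must be >= 1 SNP, got {self.window}")


@dataclass
class PRSProfile:
    """Per-sample weighted allele-dose score at one p-threshold."""

    sample_ids: list[str]
    scores: np.ndarray
    threshold_label: float
    n_variants_used: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise DegenerateDataError("non-finite PRS score")
        if len(self.scores) != len(self.sample_ids):
            raise DegenerateDataError("score / sample-id length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=f"prs_{self.threshold_label}")


def _pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise DegenerateDataError("fewer than 2 pairwise-complete samples")
    xc, yc = x[mask], y[mask]
    if xc.std() == 0 or yc.std() == 0:
        raise DegenerateDataError("zero-variance variant in r2 computation")
    r = np.corrcoef(xc, yc)[0, 1]
    return float(r * r)


def ld_r2(panel: GenotypePanel, i, j) -> float:
    """Squared Pearson correlation of doses over pairwise-complete samples.

    ``i``/``j`` may be variant ids or column indices.
    """
    i = panel.variant_index(i) if isinstance(i, str) else int(i)
    j = panel.variant_index(j) if isinstance(j, str) else int(j)
    return _pairwise_complete_r2(panel.dosages[:, i], panel.dosages[:, j])


def prune_ld(
    panel: GenotypePanel,
    weights: HarmonizedWeights,
    cfg: PruneConfig = PruneConfig(),
) -> list[str]:
    """Greedy LD prune of the harmonized variant set; returns kept ids in
    panel order.

    Visiting order is ascending training p-value (ties broken by panel
    position), or plain panel order when ``cfg.p_informed`` is False.  A
    candidate is kept iff its r-squared with every already-kept variant
    within +/-``cfg.window`` panel positions is <= ``cfg.r2_max``.
    Monomorphic variants cannot be scored against and are dropped.
    """
    pos = {v: k for k, v in panel.variants["id"].items()}
    tab = weights.table[weights.table["snp"].isin(pos)].copy()
    tab["pos"] = tab["snp"].map(pos)
    if cfg.p_informed:
        tab = tab.sort_values(["p", "pos"], kind="mergesort")
    else:
        tab = tab.sort_values("pos", kind="mergesort")

    D = panel.dosages
    n = D.shape[0]
    complete = not np.isnan(D).any()
    if complete:
        sd_all = D.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = (D - D.mean(axis=0)) / sd_all  # monomorphic columns become NaN
    else:
        sd_all = np.array([np.nanstd(D[:, j]) for j in range(D.shape[1])])

    def _r2(j: int, kj: int) -> float:
        if complete:
            return float(Z[:, j] @ Z[:, kj] / n) ** 2
        return _pairwise_complete_r2(D[:, j], D[:, kj])

    kept_pos: list[int] = []
    kept_arr = np.empty(len(tab), dtype=int)
    for snp, p, j in tab[["snp", "p", "pos"]].itertuples(index=False):
        if sd_all[j] == 0:
            continue  # monomorphic: no LD defined, cannot be retained
        karr = kept_arr[: len(kept_pos)]
        win = karr[np.abs(karr - j) <= cfg.window]
        if win.size == 0:
            ok = True
        elif complete:
            r2s = (Z[:, win].T @ Z[:, j] / n) ** 2
            ok = bool((r2s <= cfg.r2_max).all())
        else:
            ok = all(_r2(j, kj) <= cfg.r2_max for kj in win)
        if ok:
            kept_arr[len(kept_pos)] = j
            kept_pos.append(j)
    kept_pos.sort()
    ids = panel.variants["id"]
    return [ids.iloc[j] for j in kept_pos]


def compute_prs(
    panel: GenotypePanel,
    weights: HarmonizedWeights,
    kept_ids: list[str],
    threshold_label: float = 1.0,
) -> PRSProfile:
    """Weighted allele-dose sum over ``kept_ids``.

    Missing doses are imputed as twice the variant's allele frequency, the
    expected dose under Hardy-Weinberg.
    """
    wmap = dict(zip(weights.table["snp"], weights.table["weight"]))
    unknown = [v for v in kept_ids if v not in wmap]
    if unknown:
        raise ConfigError(f"kept ids not in harmonized weights: {unknown[:3]}...")
    if not kept_ids:
        warnings.warn("empty variant set: PRS is identically zero", stacklevel=2)
        return PRSProfile(list(panel.samples), np.zeros(panel.n_samples), threshold_label, 0)
    cols = [panel.variant_index(v) for v in kept_ids]
    D = panel.dosages[:, cols].copy()
    if np.isnan(D).any():
        freqs = np.array([panel.allele_frequency(v) for v in kept_ids])
        idx = np.where(np.isnan(D))
        D[idx] = 2.0 * np.take(freqs, idx[1])
    w = np.array([wmap[v] for v in kept_ids])
    return PRSProfile(list(panel.samples), D @ w, threshold_label, len(kept_ids))


def standardize_scores(profile: PRSProfile) -> PRSProfile:
    """Z-score the profile (mean 0, sample SD 1, ddof=1)."""
    if len(profile.scores) < 2:
        raise DegenerateDataError("need >= 2 samples to standardize scores")
    sd = profile.scores.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant scores cannot be standardized")
    z = (profile.scores - profile.scores.mean()) / sd
    return replace(profile, scores=z)


class PolygenicScorer(BaseEstimator, TransformerMixin):
    """Clump-and-threshold PRS as a transformer: fit selects and aligns the
    SNP set on a genotype panel; transform returns per-sample scores.

    Parameters
    ----------
    sumstats : SummaryStats
        Training-GWAS effects (log odds ratios and p-values).
    p_threshold : float, default 0.5
        Inclusion threshold on the training p-value.
    r2_max, window : LD-pruning parameters (see :class:`PruneConfig`).
    drop_ambiguous : drop strand-ambiguous A/T and C/G variants.
    standardize : return z-scored profiles (mean 0, SD 1).
    p_informed : clumping-style visiting order during pruning.

    Attributes
    ----------
    weights_ : HarmonizedWeights restricted to the threshold.
    kept_ids_ : variant ids surviving LD pruning, in panel order.
    n_variants_ : number of scored variants.
    """

    def __init__(
        self,
        sumstats: SummaryStats = None,
        p_threshold: float = 0.5,
        r2_max: float = 0.25,
        window: int = 200,
        drop_ambiguous: bool = True,
        standardize: bool = True,
        p_informed: bool = True,
    ):
        self.sumstats = sumstats
        self.p_threshold = p_threshold
        self.r2_max = r2_max
        self.window = window
        self.drop_ambiguous = drop_ambiguous
        self.standardize = standardize
        self.p_informed = p_informed

    def fit(self, X: GenotypePanel, y=None):
        if self.sumstats is None:
            raise ConfigError("PolygenicScorer requires sumstats")
        sel = threshold_select(self.sumstats, self.p_threshold)
        harm = harmonize(sel, X, drop_ambiguous=self.drop_ambiguous)
        cfg = PruneConfig(self.r2_max, self.window, self.p_informed)
        self.weights_ = harm
        self.kept_ids_ = prune_ld(X, harm, cfg)
        self.n_variants_ = len(self.kept_ids_)
        return self

    def transform(self, X: GenotypePanel) -> np.ndarray:
        if not hasattr(self, "kept_ids_"):
            raise RuntimeError("PolygenicScorer is not fitted")
        prof = compute_prs(X, self.weights_, self.kept_ids_, self.p_threshold)
        if self.standardize and prof.n_variants_used > 0:
            prof = standardize_scores(prof)
        return prof.scores.reshape(-1, 1)

    def profile(self, X: GenotypePanel) -> PRSProfile:
        """Like transform, but returns the full :class:`PRSProfile`."""
        prof = compute_prs(X, self.weights_, self.kept_ids_, self.p_threshold)
        if self.standardize and prof.n_variants_used > 0:
            prof = standardize_scores(prof)
        return prof
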
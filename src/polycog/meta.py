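"""Inverse-variance meta-analysis of standardized regression coefficients.

The fixed-effects pooled estimate weights each study by the inverse of its
squared standard error: ``w_i = 1/se_i^2``, pooled beta ``= sum(w b)/sum(w)``,
pooled se ``= 1/sqrt(sum w)``.  Between-study heterogeneity is quantified by
Cochran's Q (chi-square with k-1 df under homogeneity) and the I-squared
statistic ``I2 = max(0, 100 (Q - df)/Q)``, the percentage of between-study
variability attributable to heterogeneity rather than chance.  A
DerSimonian-Laird random-effects variant is available as a toggle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError

__all__ = ["MetaResult", "fixed_effect_meta", "heterogeneity"]


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    k: int
    Q: float
    df: int
    Q_p: float
    I2: float
    tau2: float = 0.0
    method: str = "fixed"

    def as_dict(self) -> dict:
        return {
            "k": self.k, "beta": self.beta, "se": self.se, "z": self.z,
            "p": self.p, "Q": self.Q, "Q_p": self.Q_p, "I2": self.I2,
        }


def _validate(estimates) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(estimates), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ConfigError("estimates must be a non-empty list of (beta, se) pairs")
    betas, ses = arr[:, 0], arr[:, 1]
    if not np.isfinite(betas).all() or not np.isfinite(ses).all():
        raise ConfigError("non-finite beta or se")
    if (ses <= 0).any():
        raise ConfigError("all standard errors must be positive")
    return betas, ses


def heterogeneity(estimates) -> tuple[float, int, float, float]:
    """Cochran's Q, its df and chi-square p, and I-squared (percent).

    Q is computed about the fixed-effects pooled estimate with inverse-
    variance weights.
    """
    betas, ses = _validate(estimates)
    k = betas.size
    if k < 2:
        raise DegenerateDataError("heterogeneity needs at least 2 studies")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - pooled) ** 2))
    df = k - 1
    Q_p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, Q_p, I2


def fixed_effect_meta(estimates, method: str = "fixed") -> MetaResult:
    """Pool per-study ``(beta, se)`` pairs.

    ``method='fixed'`` is inverse-variance fixed-effects pooling;
    ``method='dersimonian-laird'`` adds the DL moment estimate of the
    between-study variance tau2 to each study variance before pooling.
    A single study is returned unchanged with Q = 0.
    """
    betas, ses = _validate(estimates)
    k = betas.size
    if k == 1:
        b, s = float(betas[0]), float(ses[0])
        z = b / s
        return MetaResult(b, s, z, float(2 * stats.norm.sf(abs(z))),
                          1, 0.0, 0, 1.0, 0.0, 0.0, method)

    Q, df, Q_p, I2 = heterogeneity(estimates)
    w = 1.0 / ses**2
    tau2 = 0.0
    if method == "dersimonian-laird":
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
        w = 1.0 / (ses**2 + tau2)
    elif method != "fixed":
        raise ConfigError(f"unknown meta-analysis method {method!r}")

    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(pooled, se, z, p, k, Q, df, Q_p, I2, tau2, method)


def forest_table(labels, estimates, level: float = 0.95) -> pd.DataFrame:
    """Per-study betas with normal confidence intervals, forest-plot-ready."""
    betas, ses = _validate(estimates)
    zq = stats.norm.ppf(0.5 + level / 2)
    return pd.DataFrame({
        "study": list(labels),
        "beta": betas,
        "se": ses,
        "ci_low": betas - zq * ses,
        "ci_high": betas + zq * ses,
    })
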
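"""Derived cognitive phenotypes.

Composites follow the convention used by cognitive-epidemiology cohorts:
standardize each test, take the first unrotated principal component of the
complete cases, and orient it so that a higher composite means better
performance (mean loading positive).  Outliers beyond +/-3.5 SD from the
mean are excluded in a single pass before analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateDataError

__all__ = [
    "CompositePC1",
    "composite_pc1",
    "exclude_outliers",
    "point_biserial",
]


class CompositePC1(BaseEstimator, TransformerMixin):
    """First unrotated principal component of standardized test scores.

    Rows with any missing test are excluded from fitting and scored as
    missing.  The component is sign-oriented so the mean loading is
    positive.

    Attributes
    ----------
    loadings_ : pandas.Series, per-test loadings (unit-norm eigenvector).
    explained_variance_ratio_ : float, share of total variance on PC1.
    means_, sds_ : standardization parameters from the complete cases.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise DegenerateDataError("composite needs at least 2 tests")
        complete = X.dropna()
        if len(complete) < 3:
            raise DegenerateDataError(
                f"composite needs >= 3 complete rows, got {len(complete)}"
            )
        sd = complete.std(ddof=1)
        degenerate = sd[sd == 0].index.tolist()
        if len(X.columns) - len(degenerate) < 2:
            raise DegenerateDataError(
                f"fewer than 2 non-degenerate tests (constant: {degenerate})"
            )
        if degenerate:
            warnings.warn(f"dropping constant test column(s) {degenerate}", stacklevel=2)
            complete = complete.drop(columns=degenerate)
            sd = sd.drop(index=degenerate)
        mu = complete.mean()
        Z = (complete - mu) / sd
        cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
        eigval, eigvec = np.linalg.eigh(cov)
        v = eigvec[:, -1]
        if v.mean() < 0:
            v = -v
        self.means_ = mu
        self.sds_ = sd
        self.loadings_ = pd.Series(v, index=complete.columns)
        self.explained_variance_ratio_ = float(eigval[-1] / eigval.sum())
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("CompositePC1 is not fitted")
        X = pd.DataFrame(X)[self.loadings_.index]
        Z = (X - self.means_) / self.sds_
        scores = Z.to_numpy() @ self.loadings_.to_numpy()
        scores[X.isna().any(axis=1).to_numpy()] = np.nan
        return scores


def composite_pc1(score_table: pd.DataFrame) -> tuple[pd.Series, pd.Series, float]:
    """First-PC composite of a samples x tests table.

    Returns ``(composite, loadings, variance_explained)``; samples with any
    missing test get a missing composite.
    """
    est = CompositePC1().fit(score_table)
    comp = pd.Series(est.transform(score_table), index=pd.DataFrame(score_table).index)
    return comp, est.loadings_, est.explained_variance_ratio_


def exclude_outliers(values, k_sd: float = 3.5) -> np.ndarray:
    """Single-pass outlier mask: True = retained.

    Mean and SD are computed once over non-missing values; entries with
    ``|value - mean| > k_sd * SD`` are excluded.  Missing entries are
    retained by the mask (they are simply absent, not outlying).  Zero SD
    retains everything with a warning.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size < 3:
        raise DegenerateDataError("outlier exclusion needs >= 3 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: no outliers excluded", stacklevel=2)
        return np.ones(v.shape, dtype=bool)
    keep = np.ones(v.shape, dtype=bool)
    nz = ~np.isnan(v)
    keep[nz] = np.abs(v[nz] - obs.mean()) <= k_sd * sd
    return keep


def point_biserial(binary, continuous) -> float:
    """Point-biserial correlation: Pearson r of a 0/1 coding with a
    continuous variable, over pairwise-complete observations."""
    b = np.asarray(binary, dtype=float)
    x = np.asarray(continuous, dtype=float)
    mask = ~(np.isnan(b) | np.isnan(x))
    b, x = b[mask], x[mask]
    classes = np.unique(b)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise DegenerateDataError(f"binary variable has values {classes}, expected 0/1")
    if classes.size < 2:
        raise DegenerateDataError("binary variable has a single class")
    if x.std() == 0:
        raise DegenerateDataError("continuous variable is constant")
    return float(stats.pearsonr(b, x).statistic)
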
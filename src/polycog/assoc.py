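"""Covariate-adjusted association of polygenic scores with phenotypes.

Unrelated cohorts use ordinary least squares; family cohorts use a
univariate linear mixed model

    y = X beta + g + e,    Var(y) = sigma2_g * A + sigma2_e * I,

where A is the pedigree additive-relationship matrix (twice the kinship).
Variance components are estimated by REML: a single eigendecomposition
A = U D U' rotates the model so the covariance is diagonal, and the
restricted likelihood is profiled down to the scalar ratio
lambda = sigma2_g / sigma2_e, maximized by bounded search on log-lambda.
Fixed effects and their covariance come from generalized least squares at
the optimum; per-coefficient inference is the Wald z against the standard
normal.  Binary outcomes are analysed by the same linear (probability)
model by default.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DegenerateDataError
from .genopanel import GenotypePanel

__all__ = [
    "RelationshipMatrix",
    "VarianceComponents",
    "AssociationResult",
    "kinship_from_pedigree",
    "reml_fit",
    "wald_test",
    "wald_p",
    "linear_assoc",
    "single_snp_scan",
    "KinshipMixedModel",
]

FOUNDER_CODES = {"0", "", "NA", "nan", "None"}
LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class RelationshipMatrix:
    """Pedigree-expected additive relationship matrix A (twice the kinship)."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ConfigError("relationship matrix shape does not match ids")
        if np.abs(self.A - self.A.T).max() > 1e-10:
            raise ConfigError("relationship matrix is not symmetric")
        if (np.diag(self.A) < 1.0 - 1e-10).any():
            raise ConfigError("relationship diagonal below 1")

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(list(ids), self.A[np.ix_(idx, idx)])


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    boundary: bool = False

    @property
    def lam(self) -> float:
        return self.sigma2_g / self.sigma2_e if self.sigma2_e > 0 else np.inf

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else np.nan


@dataclass
class FitResult:
    """Fixed-effect estimates with covariance, plus variance components."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    varcomp: VarianceComponents | None
    n: int
    method: str


@dataclass
class AssociationResult:
    trait: str
    threshold: float
    beta: float
    se: float
    z: float
    p: float
    n: int
    coefficient: str = "predictor"

    def as_dict(self) -> dict:
        return {
            "trait": self.trait, "threshold": self.threshold,
            "beta": self.beta, "se": self.se, "z": self.z, "p": self.p,
            "n": self.n,
        }


# -- pedigree kinship ----------------------------------------------------


def _is_founder_code(x) -> bool:
    return pd.isna(x) or str(x).strip() in FOUNDER_CODES


def kinship_from_pedigree(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular (Henderson) method.

    *pedigree* needs columns ``id``, ``father``, ``mother``; parent code
    ``0``/NA marks a founder.  Parents referenced but absent from the id
    column are treated as founders with a warning.  Rows may appear in any
    order; a topological sort places parents before offspring, and a cycle
    raises an error.  Founders get ``A_ii = 1``; otherwise
    ``A_ii = 1 + 0.5 * A(father, mother)`` and
    ``A_ij = 0.5 * (A(father, j) + A(mother, j))`` for earlier ``j``.
    """
    ped = pedigree.reset_index(drop=True)
    for col in ("id", "father", "mother"):
        if col not in ped.columns:
            raise ConfigError(f"pedigree missing column {col!r}")
    ids = [str(s) for s in ped["id"]]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sample id in pedigree")
    pos = {s: i for i, s in enumerate(ids)}

    parents: list[tuple[int | None, int | None]] = []
    for f, m in zip(ped["father"], ped["mother"]):
        pf = None if _is_founder_code(f) else str(f).strip()
        pm = None if _is_founder_code(m) else str(m).strip()
        for p in (pf, pm):
            if p is not None and p not in pos:
                warnings.warn(
                    f"parent {p!r} not in pedigree; treated as founder",
                    stacklevel=2,
                )
        parents.append(
            (pos.get(pf) if pf is not None else None,
             pos.get(pm) if pm is not None else None)
        )

    # Kahn topological sort over the parent -> child edges
    n = len(ids)
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (f, m) in enumerate(parents):
        for p in (f, m):
            if p is not None:
                indeg[i] += 1
                children[p].append(i)
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    while queue:
        i = queue.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        raise ConfigError("pedigree contains a cycle")

    A = np.zeros((n, n))
    done: list[int] = []
    done_arr = np.empty(n, dtype=int)
    for i in order:
        f, m = parents[i]
        prev = done_arr[: len(done)]
        row = np.zeros(len(done))
        if f is not None:
            row += 0.5 * A[f, prev]
        if m is not None:
            row += 0.5 * A[m, prev]
        A[i, prev] = row
        A[prev, i] = row
        A[i, i] = 1.0 + (0.5 * A[f, m] if f is not None and m is not None else 0.0)
        done_arr[len(done)] = i
        done.append(i)
    return RelationshipMatrix(ids, A)


# -- REML linear mixed model ---------------------------------------------

_EIG_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}
_EIG_CACHE_MAX = 8


def kinship_eig(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cached eigendecomposition (d, U) of a relationship matrix.

    The same pedigree is reused across traits, thresholds and replicates;
    the decomposition dominates the cost of a fit, so a small keyed cache
    pays for itself.
    """
    key = hashlib.sha1(np.ascontiguousarray(A).tobytes()).hexdigest()
    if key not in _EIG_CACHE:
        if len(_EIG_CACHE) >= _EIG_CACHE_MAX:
            _EIG_CACHE.pop(next(iter(_EIG_CACHE)))
        d, U = np.linalg.eigh(A)
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise ConfigError(
                f"relationship matrix is not positive semi-definite "
                f"(min eigenvalue {d.min():.3g})"
            )
        _EIG_CACHE[key] = (np.clip(d, 0.0, None), U)
    return _EIG_CACHE[key]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, cur = [], np.empty((X.shape[0], 0))
        r = 0
        for j, name in enumerate(names):
            cand = np.column_stack([cur, X[:, j]])
            rr = np.linalg.matrix_rank(cand)
            if rr > r:
                cur, r = cand, rr
            else:
                bad.append(name)
        raise DegenerateDataError(f"design matrix rank-deficient; collinear columns: {bad}")


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | RelationshipMatrix | None = None,
    names: list[str] | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-8,
) -> FitResult:
    """REML fit of ``y = X beta + g + e`` with ``Var(g) = sigma2_g A``.

    The restricted likelihood is profiled to lambda = sigma2_g/sigma2_e and
    maximized on log-lambda over ``[1e-6, 1e6]`` by bounded scalar search
    (tolerance 1e-8); solutions at the bounds are flagged as boundary (an
    unidentifiable or null variance split).  Pass ``eig=(d, U)`` to reuse a
    precomputed eigendecomposition.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if n != y.size:
        raise ConfigError("y and X have different numbers of rows")
    if n <= p:
        raise DegenerateDataError(f"need n > p, got n={n}, p={p}")
    _check_full_rank(X, names)

    if eig is None:
        Amat = A.A if isinstance(A, RelationshipMatrix) else np.asarray(A, dtype=float)
        d, U = kinship_eig(Amat)
    else:
        d, U = eig
    ys = U.T @ y
    Xs = U.T @ X

    def neg_restricted_loglik(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = 1.0 / (lam * d + 1.0)
        Xw = Xs * w[:, None]
        XtWX = Xs.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (w * r))
        sigma2_e = rss / (n - p)
        _, logdet_xx = np.linalg.slogdet(XtWX)
        return 0.5 * (
            (n - p) * np.log(sigma2_e)
            + np.sum(np.log(lam * d + 1.0))
            + logdet_xx
            + (n - p)
        )

    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = optimize.minimize_scalar(
        neg_restricted_loglik, bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    log_lam = float(res.x)
    # the bounded search can stall marginally inside a flat boundary region
    for cand in (lo, hi):
        if neg_restricted_loglik(cand) < neg_restricted_loglik(log_lam):
            log_lam = cand
    lam = float(np.exp(log_lam))
    boundary = log_lam <= lo + 10 * tol or log_lam >= hi - 10 * tol
    # a flat profile (e.g. A = I) means the variance split is unidentifiable
    if not boundary:
        f_opt = neg_restricted_loglik(log_lam)
        if max(abs(neg_restricted_loglik(lo) - f_opt),
               abs(neg_restricted_loglik(hi) - f_opt)) < 1e-6:
            boundary = True

    w = 1.0 / (lam * d + 1.0)
    Xw = Xs * w[:, None]
    XtWX = Xs.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (Xw.T @ ys)
    r = ys - Xs @ beta
    sigma2_e = float(r @ (w * r)) / (n - p)
    sigma2_g = lam * sigma2_e
    cov = sigma2_e * XtWX_inv
    vc = VarianceComponents(sigma2_g, sigma2_e, -float(res.fun), boundary)
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        varcomp=vc,
        n=n,
        method="reml-lmm",
    )


def ols_fit(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> FitResult:
    """OLS with Wald (normal) inference, via statsmodels."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] <= X.shape[1]:
        raise DegenerateDataError("need more observations than parameters")
    _check_full_rank(X, names)
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    return FitResult(
        params=fit.params,
        bse=fit.bse,
        cov=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        varcomp=None,
        n=int(fit.nobs),
        method="ols",
    )


# -- Wald inference ------------------------------------------------------


def wald_p(z: float) -> float:
    """Two-sided standard-normal tail probability: ``2 * Phi(-|z|)``."""
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_test(fit: FitResult, coefficient: str) -> tuple[float, float]:
    """Wald z and two-sided p for one fixed-effect coefficient."""
    if coefficient not in fit.params.index:
        raise ConfigError(f"coefficient {coefficient!r} not in fit")
    se = float(fit.bse[coefficient])
    if se == 0:
        raise DegenerateDataError(f"zero standard error for {coefficient!r}")
    z = float(fit.params[coefficient]) / se
    return z, wald_p(z)


# -- high-level association ----------------------------------------------


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


def linear_assoc(
    y,
    predictor,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
    interaction: str | None = None,
    kinship: RelationshipMatrix | None = None,
    sample_ids: list[str] | None = None,
    trait: str = "y",
    threshold: float = float("nan"),
    binary_model: str = "linear",
) -> AssociationResult:
    """Association of one predictor with one outcome, covariate-adjusted.

    With *standardize*, outcome and predictor are z-scored over the complete
    cases so the reported beta is a standardized regression coefficient; a
    0/1 outcome is left on its own scale (linear probability model) unless
    ``binary_model='logistic'``.  With *kinship*, the model is the REML
    linear mixed model with the pedigree relationship matrix as the random
    effect; otherwise OLS.  *interaction* names a covariate whose product
    with the predictor is added and tested instead of the main effect.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame(index=range(len(y)))
    if len(y) != len(x) or len(cov) != len(y):
        raise ConfigError("outcome, predictor and covariates differ in length")
    if interaction is not None and interaction not in cov.columns:
        raise ConfigError(f"interaction covariate {interaction!r} not found")

    mask = ~(np.isnan(y) | np.isnan(x) | cov.isna().any(axis=1).to_numpy())
    n = int(mask.sum())
    p_fixed = 2 + cov.shape[1] + (1 if interaction is not None else 0)
    if n < p_fixed + 2:
        raise DegenerateDataError(f"only {n} complete cases for {p_fixed} parameters")
    y, x, cov = y[mask], x[mask], cov.loc[mask].reset_index(drop=True)

    uy = np.unique(y)
    is_binary = uy.size <= 2 and np.isin(uy, (0.0, 1.0)).all()
    if is_binary and uy.size < 2:
        raise DegenerateDataError("binary outcome has a single class")

    if standardize:
        x = _zscore(x)
        if not is_binary:
            y = _zscore(y)

    names = ["intercept", "predictor"] + [str(c) for c in cov.columns]
    Xd = np.column_stack([np.ones(n), x, cov.to_numpy(dtype=float)])
    test_coef = "predictor"
    if interaction is not None:
        Xd = np.column_stack([Xd, x * cov[interaction].to_numpy(dtype=float)])
        names.append(f"predictor:{interaction}")
        test_coef = f"predictor:{interaction}"

    if is_binary and binary_model == "logistic":
        import statsmodels.api as sm

        fit_sm = sm.Logit(y, pd.DataFrame(Xd, columns=names)).fit(disp=0)
        fit = FitResult(fit_sm.params, fit_sm.bse,
                        pd.DataFrame(fit_sm.cov_params(), index=names, columns=names),
                        None, n, "logistic")
    elif kinship is not None:
        if sample_ids is None:
            if list(kinship.ids) and len(kinship.ids) == mask.size:
                sample_ids = list(kinship.ids)
            else:
                raise ConfigError("sample_ids required to align kinship with data")
        kept_ids = [s for s, keep in zip(sample_ids, mask) if keep]
        K = kinship.subset(kept_ids)
        fit = reml_fit(y, Xd, A=K, names=names)
    else:
        fit = ols_fit(y, Xd, names=names)

    z, p = wald_test(fit, test_coef)
    return AssociationResult(
        trait=trait, threshold=threshold,
        beta=float(fit.params[test_coef]), se=float(fit.bse[test_coef]),
        z=z, p=p, n=n, coefficient=test_coef,
    )


def single_snp_scan(
    panel: GenotypePanel,
    snp_ids: list[str],
    y,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
    kinship: RelationshipMatrix | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP association of allele dose with the outcome, in input order.

    Absent or monomorphic SNPs are skipped with a log entry.  Raw p-values
    are reported without multiplicity adjustment.
    """
    log = log if log is not None else []
    rows = []
    for snp in snp_ids:
        try:
            j = panel.variant_index(snp)
        except KeyError:
            log.append(f"scan: {snp} absent from panel, skipped")
            continue
        dose = panel.dosages[:, j]
        obs = dose[~np.isnan(dose)]
        if obs.size == 0 or obs.std() == 0:
            log.append(f"scan: {snp} monomorphic, skipped")
            continue
        res = linear_assoc(
            y, dose, covariates, standardize=standardize,
            kinship=kinship, sample_ids=list(panel.samples), trait=snp,
        )
        rows.append({"snp": snp, **res.as_dict()})
    return pd.DataFrame(rows)


# -- sklearn-style estimator ---------------------------------------------


class KinshipMixedModel:
    """sklearn-style regressor wrapping the pedigree-REML mixed model.

    Parameters
    ----------
    kinship : RelationshipMatrix or ndarray or None
        Random-effect covariance; None degenerates to OLS (Var = sigma2 I).
    add_intercept : bool, prepend a constant column.

    Attributes (after fit)
    ----------------------
    coef_, intercept_, bse_ : fixed-effect estimates and standard errors.
    sigma2_g_, sigma2_e_, heritability_ : variance components.
    fit_result_ : full :class:`FitResult`.
    """

    def __init__(self, kinship=None, add_intercept: bool = True):
        self.kinship = kinship
        self.add_intercept = add_intercept

    def get_params(self, deep: bool = True) -> dict:
        return {"kinship": self.kinship, "add_intercept": self.add_intercept}

    def set_params(self, **params) -> "KinshipMixedModel":
        for k, v in params.items():
            if k not in ("kinship", "add_intercept"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        names = [f"x{j}" for j in range(X.shape[1])]
        if self.add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + names
        if self.kinship is None:
            A = np.eye(len(y))
        elif isinstance(self.kinship, RelationshipMatrix):
            A = self.kinship.A
        else:
            A = np.asarray(self.kinship, dtype=float)
        fit = reml_fit(y, X, A=A, names=names)
        self.fit_result_ = fit
        params = fit.params.to_numpy()
        if self.add_intercept:
            self.intercept_, self.coef_ = float(params[0]), params[1:]
        else:
            self.intercept_, self.coef_ = 0.0, params
        self.bse_ = fit.bse.to_numpy()
        self.sigma2_g_ = fit.varcomp.sigma2_g
        self.sigma2_e_ = fit.varcomp.sigma2_e
        self.heritability_ = fit.varcomp.heritability
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("KinshipMixedModel is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_
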
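"""Genotype panels: dosage I/O, allele frequencies, stratification components.

A :class:`GenotypePanel` holds a samples x variants matrix of counted-allele
doses (0/1/2, NaN for missing) together with per-variant metadata.  The
counted allele is the VCF ALT allele throughout; a dose of 2 means two
copies of ALT.  Population structure is summarised by principal components
of the centred, variance-standardised dosage matrix ("MDS components" in the
epidemiological literature — for Euclidean dosage distance classical metric
MDS spans the same subspace, PCA is used for determinism and cost).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateDataError, FormatError

__all__ = [
    "GenotypePanel",
    "read_genotypes",
    "allele_frequency",
    "stratification_components",
    "StratificationPCA",
]

_VARIANT_COLUMNS = ("id", "ref", "alt")


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows of ``dosages``).
    variants : pandas.DataFrame
        One row per variant, columns ``id`` (unique), ``ref``, ``alt``;
        row order is genomic order and defines the position index used by
        windowed LD operations.
    dosages : ndarray of float, shape (n_samples, n_variants)
        Counted-allele (ALT) dose in {0, 1, 2}; NaN marks a missing genotype.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise FormatError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("sample ids are not unique")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate variant id {dup!r}")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages[~ok].flat[0]
            raise FormatError(f"dosage value {bad!r} not in {{0,1,2,NaN}}")
        self._id_index: dict | None = None

    # -- basic queries ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        if self._id_index is None:
            object.__setattr__(
                self, "_id_index",
                {v: j for j, v in enumerate(self.variants["id"])},
            )
        try:
            return self._id_index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def allele_frequency(self, variant_id: str) -> float:
        """Counted-allele (ALT) frequency over non-missing samples."""
        j = self.variant_index(variant_id)
        col = self.dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise DegenerateDataError(
                f"variant {variant_id!r}: all genotypes missing, "
                "allele frequency undefined"
            )
        return float(obs.mean() / 2.0)

    def allele_frequencies(self) -> np.ndarray:
        """ALT frequency per variant (vectorised; NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        if np.isnan(freq).any():
            j = int(np.flatnonzero(np.isnan(freq))[0])
            raise DegenerateDataError(
                f"variant {self.variants['id'].iloc[j]!r}: all genotypes missing"
            )
        return freq

    def fingerprint(self) -> str:
        """Short content hash used in run logs."""
        h = hashlib.sha256()
        h.update(",".join(self.samples).encode())
        h.update(",".join(self.variants["id"]).encode())
        h.update(np.nan_to_num(self.dosages, nan=-1.0).tobytes())
        return h.hexdigest()[:12]

    # -- writers ---------------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        """Write sample x variant dosage TSV (header: variant ids, first
        column ``sample``; missing as NA)."""
        df = pd.DataFrame(self.dosages, columns=self.variants["id"].tolist())
        df.insert(0, "sample", self.samples)
        with np.errstate(invalid="ignore"):
            for c in df.columns[1:]:
                df[c] = df[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        df.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path) -> None:
        """Write a minimal unphased-GT VCF (single contig '1', positions are
        1-based panel order)."""
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for j, row in self.variants.iterrows():
                gts = [
                    "./." if np.isnan(d) else gt_codes[d]
                    for d in self.dosages[:, j]
                ]
                fh.write(
                    f"1\t{j + 1}\t{row['id']}\t{row['ref']}\t{row['alt']}\t"
                    f".\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


# -- readers -------------------------------------------------------------


def _read_vcf(path, log: list[str]) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, refs, alts, rows = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.append(f"skipped multi-allelic record {rec.ID or rec.POS}")
            continue
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        doses = np.full(len(samples), np.nan)
        for i, g in enumerate(rec.genotypes):
            a = [x for x in g[:-1] if x >= 0]
            if len(a) == 2:
                doses[i] = float(sum(1 for x in a if x == 1))
        rows.append(doses)
    vcf.close()
    variants = pd.DataFrame({"id": ids, "ref": refs, "alt": alts})
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypePanel(samples, variants, dosages)


def _read_dosage_tsv(path, log: list[str]) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: dosage TSV needs a sample column plus variants")
    samples = df.iloc[:, 0].tolist()
    variant_ids = list(df.columns[1:])
    mat = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # alleles are not carried by the dosage dialect; callers harmonize by id
    variants = pd.DataFrame(
        {"id": variant_ids, "ref": ["N"] * len(variant_ids), "alt": ["N"] * len(variant_ids)}
    )
    return GenotypePanel(samples, variants, mat)


def read_genotypes(path, fmt: str = "vcf", log: list[str] | None = None) -> GenotypePanel:
    """Read a genotype panel from ``vcf`` or ``dosage-tsv``.

    Unphased GT fields become ALT-allele doses; ``./.`` stays missing;
    multi-allelic VCF records are skipped (logged into *log* if given).
    """
    log = log if log is not None else []
    fmt = fmt.lower()
    try:
        if fmt == "vcf":
            return _read_vcf(path, log)
        if fmt in ("dosage-tsv", "dosage", "tsv"):
            return _read_dosage_tsv(path, log)
    except FormatError:
        raise
    except Exception as exc:  # cyvcf2/pandas parse failures
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    from .errors import ConfigError

    raise ConfigError(f"unknown genotype format {fmt!r}; use 'vcf' or 'dosage-tsv'")


def allele_frequency(panel: GenotypePanel, variant_id: str) -> float:
    """Counted-allele frequency of one variant (missing excluded)."""
    return panel.allele_frequency(variant_id)


# -- stratification components -------------------------------------------


class StratificationPCA(BaseEstimator, TransformerMixin):
    """Principal components of the standardized dosage matrix, scaled to
    unit sample variance, for use as ancestry covariates.

    Missing doses are mean-imputed *for component extraction only*.  Each
    component is deterministically sign-oriented: the variant loading of
    largest magnitude is made positive.

    Parameters
    ----------
    n_components : int
        Number of components k to extract.

    Attributes
    ----------
    components_ : ndarray (n_samples, k)
        Per-sample component scores, each with sample variance 1 (ddof=1).
    loadings_ : ndarray (n_variants_used, k)
        Right singular vectors over the variants that entered the fit.
    explained_variance_ratio_ : ndarray (k,)
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X: GenotypePanel, y=None):
        k = int(self.n_components)
        if k < 1:
            raise DegenerateDataError("n_components must be >= 1")
        if X.n_samples < k + 1:
            raise DegenerateDataError(
                f"need at least k+1={k + 1} samples for {k} components, "
                f"got {X.n_samples}"
            )
        M = X.dosages.copy()
        mu = np.nanmean(M, axis=0)
        idx = np.where(np.isnan(M))
        M[idx] = np.take(mu, idx[1])
        sd = M.std(axis=0, ddof=0)
        keep = sd > 0
        if keep.sum() < k:
            raise DegenerateDataError(
                f"only {int(keep.sum())} variants with nonzero variance; "
                f"need >= {k}"
            )
        Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
        # eigendecompose the smaller Gram matrix: same subspace as the SVD
        # of Z at a fraction of the cost
        if Z.shape[1] <= Z.shape[0]:
            evals, evecs = np.linalg.eigh(Z.T @ Z)
            evals = np.clip(evals[::-1], 0.0, None)
            V_full = evecs[:, ::-1]
            s = np.sqrt(evals)
            V = V_full[:, :k].copy()
            with np.errstate(divide="ignore", invalid="ignore"):
                U = (Z @ V) / s[:k]
        else:
            evals, evecs = np.linalg.eigh(Z @ Z.T)
            evals = np.clip(evals[::-1], 0.0, None)
            s = np.sqrt(evals)
            U = evecs[:, ::-1][:, :k].copy()
            with np.errstate(divide="ignore", invalid="ignore"):
                V = (Z.T @ U) / s[:k]
        tol = s[0] * max(Z.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int((s > tol).sum())
        if rank < k:
            raise DegenerateDataError(
                f"dosage matrix has rank {rank}; at most {rank} components "
                "are extractable"
            )
        # orient: largest-|loading| positive, then scale to unit variance
        for c in range(k):
            if V[np.argmax(np.abs(V[:, c])), c] < 0:
                U[:, c] = -U[:, c]
                V[:, c] = -V[:, c]
        comps = U / U.std(axis=0, ddof=1)
        self.components_ = comps
        self.loadings_ = V
        self.explained_variance_ratio_ = evals[:k] / evals.sum()
        self._fit_samples = list(X.samples)
        return self

    def transform(self, X: GenotypePanel) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise RuntimeError("StratificationPCA is not fitted")
        if list(X.samples) != self._fit_samples:
            raise DegenerateDataError(
                "StratificationPCA scores are in-sample; transform must be "
                "called with the fitted panel"
            )
        return self.components_


def stratification_components(panel: GenotypePanel, k: int) -> np.ndarray:
    """Top-``k`` ancestry components of *panel* (see :class:`StratificationPCA`)."""
    return StratificationPCA(n_components=k).fit(panel).components_
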
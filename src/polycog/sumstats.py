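"""GWAS summary statistics: reading, validation, harmonization, thresholding.

The TSV dialect is the common "base" format: a header row with columns
``SNP``, ``A1`` (effect allele), ``A2`` (other allele), ``OR`` or ``BETA``
(odds ratio, converted to natural-log scale on read, or log-odds directly),
``P``, and optionally ``EAF``; lines starting with ``#`` are comments.

Harmonization aligns effect alleles with a panel's counted (ALT) allele:
same orientation keeps the weight, an allele swap negates it, a strand flip
(complement) is reconciled the same way, and strand-ambiguous A/T and C/G
variants are dropped by default because their orientation cannot be
determined from alleles alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .genopanel import GenotypePanel

__all__ = [
    "SummaryStats",
    "HarmonizedWeights",
    "read_sumstats",
    "harmonize",
    "threshold_select",
]

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs look identical on both strands."""
    return _COMPLEMENT.get(a1) == a2


@dataclass
class SummaryStats:
    """Per-variant training-GWAS effects on the log-odds scale.

    ``table`` columns: ``snp``, ``a1`` (effect allele), ``a2``, ``log_or``,
    ``p``, optionally ``eaf``.  ``rejects`` records rows dropped during
    reading, one ``(line_number, reason)`` per row.
    """

    table: pd.DataFrame
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"snp", "a1", "a2", "log_or", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"summary statistics missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def threshold(self, p_cut: float) -> "SummaryStats":
        return threshold_select(self, p_cut)

    def to_tsv(self, path) -> None:
        out = self.table.rename(
            columns={"snp": "SNP", "a1": "A1", "a2": "A2", "log_or": "BETA",
                     "p": "P", "eaf": "EAF"}
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedWeights:
    """Panel-aligned scoring weights plus an exclusion log.

    ``table`` columns: ``snp``, ``weight`` (signed log-odds per counted
    allele of the panel), ``p``, ``flipped`` (True when the panel counts the
    GWAS other allele); ``exclusions`` columns: ``snp``, ``reason`` with
    reason in {unmatched, strand_ambiguous, allele_mismatch}.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.astype(
            {"weight": float, "p": float}, errors="ignore"
        )
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise FormatError("non-finite harmonized weight")
        if self.table["snp"].duplicated().any():
            raise FormatError("duplicate variant in harmonized weights")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def exclusion_counts(self) -> dict[str, int]:
        return self.exclusions["reason"].value_counts().to_dict()


def read_sumstats(path, dialect: dict | None = None) -> SummaryStats:
    """Read a summary-statistics TSV, validating and logging rejected rows.

    An ``OR`` column is converted to natural log; a ``BETA`` column is taken
    as log-odds directly.  Rows with p outside (0, 1], alleles outside
    {A,C,G,T}, identical alleles, or non-finite/non-positive OR are rejected
    and logged with their 1-based file line numbers.
    """
    colmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "p": "P",
              "or": "OR", "beta": "BETA", "eaf": "EAF"}
    if dialect:
        colmap.update({k.lower(): v for k, v in dialect.items()})
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot read summary statistics {path}: {exc}") from exc
    raw.columns = [c.strip() for c in raw.columns]

    have = {c.upper(): c for c in raw.columns}
    need = [colmap["snp"], colmap["a1"], colmap["a2"], colmap["p"]]
    missing = [c for c in need if c.upper() not in have]
    has_or = colmap["or"].upper() in have
    has_beta = colmap["beta"].upper() in have
    if not (has_or or has_beta):
        missing.append(f"{colmap['or']} or {colmap['beta']}")
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    rejects: list[tuple[int, str]] = []
    rows = []
    eff_col = have[colmap["or"].upper()] if has_or else have[colmap["beta"].upper()]
    eaf_col = have.get(colmap["eaf"].upper())
    for i, rec in raw.iterrows():
        line_no = i + 2  # 1-based, after the header
        snp = str(rec[have[colmap["snp"].upper()]]).strip()
        a1 = str(rec[have[colmap["a1"].upper()]]).strip().upper()
        a2 = str(rec[have[colmap["a2"].upper()]]).strip().upper()
        try:
            p = float(rec[have[colmap["p"].upper()]])
            eff = float(rec[eff_col])
        except (TypeError, ValueError):
            rejects.append((line_no, "non-numeric effect or p-value"))
            continue
        if a1 not in VALID_BASES or a2 not in VALID_BASES:
            rejects.append((line_no, f"invalid alleles {a1}/{a2}"))
            continue
        if a1 == a2:
            rejects.append((line_no, "effect and other allele identical"))
            continue
        if not (0.0 < p <= 1.0) or not np.isfinite(p):
            rejects.append((line_no, f"p-value {p} outside (0,1]"))
            continue
        if has_or:
            if not np.isfinite(eff) or eff <= 0:
                rejects.append((line_no, f"odds ratio {eff} not positive"))
                continue
            log_or = float(np.log(eff))
        else:
            if not np.isfinite(eff):
                rejects.append((line_no, "non-finite BETA"))
                continue
            log_or = eff
        row = {"snp": snp, "a1": a1, "a2": a2, "log_or": log_or, "p": p}
        if eaf_col is not None:
            try:
                row["eaf"] = float(rec[eaf_col])
            except (TypeError, ValueError):
                row["eaf"] = np.nan
        rows.append(row)
    cols = ["snp", "a1", "a2", "log_or", "p"] + (["eaf"] if eaf_col else [])
    table = pd.DataFrame(rows, columns=cols)
    return SummaryStats(table, rejects)


def harmonize(
    sumstats: SummaryStats,
    panel: GenotypePanel,
    drop_ambiguous: bool = True,
) -> HarmonizedWeights:
    """Align GWAS effect alleles with the panel's counted (ALT) alleles.

    Per variant (matched by id): if the panel ALT equals the effect allele
    the weight is ``+log_or``; if it equals the other allele, ``-log_or``;
    the same after complementing both GWAS alleles (strand flip).  A/T and
    C/G variants are excluded when *drop_ambiguous*; variants absent from
    the panel or with irreconcilable alleles are excluded.  Every exclusion
    is logged with a reason.
    """
    pvar = panel.variants.set_index("id")
    kept, excluded = [], []
    for rec in sumstats.table.itertuples(index=False):
        a1, a2 = rec.a1, rec.a2
        if rec.snp not in pvar.index:
            excluded.append((rec.snp, "unmatched"))
            continue
        if drop_ambiguous and is_strand_ambiguous(a1, a2):
            excluded.append((rec.snp, "strand_ambiguous"))
            continue
        ref = str(pvar.at[rec.snp, "ref"]).upper()
        alt = str(pvar.at[rec.snp, "alt"]).upper()
        pair = (alt, ref)
        if pair == (a1, a2):
            weight, flipped = rec.log_or, False
        elif pair == (a2, a1):
            weight, flipped = -rec.log_or, True
        elif pair == (complement(a1), complement(a2)):
            weight, flipped = rec.log_or, False
        elif pair == (complement(a2), complement(a1)):
            weight, flipped = -rec.log_or, True
        else:
            excluded.append((rec.snp, "allele_mismatch"))
            continue
        kept.append((rec.snp, float(weight), float(rec.p), flipped))
    table = pd.DataFrame(kept, columns=["snp", "weight", "p", "flipped"])
    exclusions = pd.DataFrame(excluded, columns=["snp", "reason"])
    return HarmonizedWeights(table, exclusions)


def threshold_select(sumstats: SummaryStats, p_cut: float) -> SummaryStats:
    """Records with ``p <= p_cut``, original order preserved."""
    if not (0.0 < p_cut <= 1.0):
        raise ConfigError(f"p-value threshold must lie in (0,1], got {p_cut}")
    sel = sumstats.table[sumstats.table["p"] <= p_cut].reset_index(drop=True)
    return SummaryStats(sel, list(sumstats.rejects))
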
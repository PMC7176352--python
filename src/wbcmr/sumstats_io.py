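"""Readers, writers and in-memory containers for GWAS summary statistics.

Conventions
-----------
* Positions are 1-based, GRCh37 — the build in which the MHC exclusion
  interval (chr6:20,000,000-40,000,000) is expressed.
* Only biallelic single-nucleotide variants are kept; indels and multi-base
  alleles are dropped (and counted) at read time.
* A missing effect-allele frequency is tolerated but flags the record:
  downstream palindrome handling must then treat the SNP as unresolvable.

Input formats are header-bearing delimited text (tab or comma,
auto-detected); column names are remapped through a ``column_map``.
LD comes in either as a square labelled r² matrix or a three-column
pairwise list.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("wbcmr.sumstats_io")

VALID_BASES = frozenset("ACGT")

#: default column names expected in a summary-statistics file
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

#: fixed column order of the results table written by :func:`write_results`
RESULT_COLUMNS = [
    "exposure", "outcome", "direction", "method", "n_snps",
    "estimate", "se", "ci_low", "ci_high", "pvalue", "fdr_q",
    "Q", "egger_intercept", "egger_intercept_p",
]


class ConfigurationError(ValueError):
    """A column mapping or option does not match the input file."""


class InputError(ValueError):
    """The input file content is unusable (zero valid rows, bad LD values...)."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association record in one GWAS."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when unknown
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.rsid}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not math.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.rsid}: eaf outside [0,1]")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.rsid}: pvalue outside (0,1]")
        if self.n < 1:
            raise ValueError(f"{self.rsid}: n must be >= 1")

    @property
    def maf(self) -> float:
        """Minor-allele frequency; NaN when eaf is unknown."""
        if math.isnan(self.eaf):
            return math.nan
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


class SumstatsTable:
    """Ordered collection of :class:`SnpAssociation`, unique by rsid.

    Thin wrapper over a pandas DataFrame so that filters stay vectorised
    while the record-level contract stays explicit.
    """

    COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pvalue", "n"]

    def __init__(self, trait_name: str, df: pd.DataFrame,
                 trait_units: str = "", n_dropped: int = 0):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sumstats frame missing columns: {missing}")
        if df["rsid"].duplicated().any():
            dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()[:5]
            raise ValueError(f"duplicate rsids in table: {dups}")
        self.trait_name = trait_name
        self.trait_units = trait_units
        self.df = df[self.COLUMNS].reset_index(drop=True)
        self.n_dropped = n_dropped

    @classmethod
    def from_records(cls, trait_name: str, records: Iterable[SnpAssociation],
                     trait_units: str = "") -> "SumstatsTable":
        rows = [vars(r) for r in records]
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        return cls(trait_name, df, trait_units=trait_units)

    def records(self) -> list[SnpAssociation]:
        return [SnpAssociation(**{k: row[k] for k in self.COLUMNS})
                for row in self.df.to_dict("records")]

    def subset(self, mask: np.ndarray | pd.Series) -> "SumstatsTable":
        """New table with the rows where ``mask`` is True, order preserved."""
        return SumstatsTable(self.trait_name, self.df.loc[np.asarray(mask)],
                             trait_units=self.trait_units)

    def get(self, rsid: str) -> SnpAssociation | None:
        hit = self.df[self.df["rsid"] == rsid]
        if hit.empty:
            return None
        return SnpAssociation(**{k: hit.iloc[0][k] for k in self.COLUMNS})

    @property
    def rsids(self) -> list[str]:
        return self.df["rsid"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SumstatsTable({self.trait_name!r}, {len(self)} SNPs)"


@dataclass
class LdMatrix:
    """Pairwise squared correlations (r²) between candidate instruments."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match rsid count")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise InputError("r2 entries must lie in [0,1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise InputError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise InputError("r2 diagonal must be 1")
        # canonicalize after tolerance checks
        self.r2 = (self.r2 + self.r2.T) / 2.0
        np.fill_diagonal(self.r2, 1.0)
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float:
        """r² between two rsids; pairs absent from the panel count as 0."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LdMatrix":
        return cls(list(rsids), np.eye(len(rsids)))


# ---------------------------------------------------------------------------
# reading


def _sniff_delimiter(path: str, override: str | None = None) -> str:
    if override is not None:
        return override
    with open(path, "r", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_sumstats(path: str, column_map: Mapping[str, str] | None = None,
                  trait_name: str = "", trait_units: str = "",
                  delimiter: str | None = None) -> SumstatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps the canonical field names (``rsid``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
    ``pvalue``, ``n``) to the column names present in the file; unmapped
    fields fall back to the defaults (rsid, chr, pos, ea, oa, eaf, beta,
    se, pval, n). Rows failing validation (non-ACGT or multi-base alleles,
    se <= 0, p outside (0,1], eaf outside [0,1] ...) are dropped and counted;
    an entirely invalid file raises :class:`InputError`. Alleles are
    upper-cased; ``eaf`` may be empty (kept as NaN, flagged downstream).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown field names in column_map: {sorted(unknown)}")
        colmap.update(column_map)

    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) {missing} not found; file has {list(raw.columns)}")

    df = pd.DataFrame({field: raw[col] for field, col in colmap.items()})
    n_rows = len(df)

    df["rsid"] = df["rsid"].astype(str).str.strip()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.strip().str.upper()
    for c in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    ok = (
        df["rsid"].ne("")
        & df["effect_allele"].isin(VALID_BASES)
        & df["other_allele"].isin(VALID_BASES)
        & (df["effect_allele"] != df["other_allele"])
        & df["pos"].notna() & (df["pos"] >= 1)
        & df["beta"].notna() & np.isfinite(df["beta"])
        & df["se"].notna() & (df["se"] > 0)
        & df["pvalue"].notna() & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & df["n"].notna() & (df["n"] >= 1)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    # duplicated rsids: keep first occurrence, drop the rest
    ok &= ~df["rsid"].duplicated(keep="first")

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d of %d rows failing validation", path, n_dropped, n_rows)
    df = df.loc[ok].copy()
    if df.empty:
        raise InputError(f"{path}: no valid summary-statistics rows")
    df["pos"] = df["pos"].astype(int)
    n_missing_eaf = int(df["eaf"].isna().sum())
    if n_missing_eaf:
        logger.warning("%s: %d records lack eaf; palindrome checks will drop them",
                       path, n_missing_eaf)
    return SumstatsTable(trait_name or path, df, trait_units=trait_units,
                         n_dropped=n_dropped)


def read_ld(path: str, rsids: Sequence[str] | None = None,
            delimiter: str | None = None) -> LdMatrix:
    """Read an LD (r²) table, square labelled matrix or 3-column pairwise list.

    Pairwise form: columns (rsid_a, rsid_b, r2); the rsid universe is the
    union of listed rsids unless ``rsids`` is given explicitly, absent pairs
    default to r²=0 and self-pairs are forced to 1. Square form: rsid labels
    in the header and first column; asymmetry beyond 1e-8 or entries outside
    [0,1] raise :class:`InputError`.
    """
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep)
    if raw.shape[1] == 3 and not _looks_square(raw):
        a = raw.iloc[:, 0].astype(str)
        b = raw.iloc[:, 1].astype(str)
        val = pd.to_numeric(raw.iloc[:, 2], errors="coerce")
        if val.isna().any():
            raise InputError(f"{path}: non-numeric r2 in pairwise list")
        if ((val < 0) | (val > 1)).any():
            raise InputError(f"{path}: r2 outside [0,1]")
        universe = list(rsids) if rsids is not None else sorted(set(a) | set(b))
        idx = {r: i for i, r in enumerate(universe)}
        m = np.zeros((len(universe), len(universe)))
        for ra, rb, v in zip(a, b, val):
            if ra not in idx or rb not in idx:
                logger.info("%s: pair (%s,%s) outside rsid universe, ignored", path, ra, rb)
                continue
            m[idx[ra], idx[rb]] = v
            m[idx[rb], idx[ra]] = v
        np.fill_diagonal(m, 1.0)
        return LdMatrix(universe, m)

    # square labelled matrix
    raw = pd.read_csv(path, sep=sep, index_col=0)
    labels = [str(c) for c in raw.columns]
    if [str(i) for i in raw.index] != labels:
        raise InputError(f"{path}: square LD matrix row labels do not match column labels")
    m = raw.to_numpy(dtype=float)
    if np.isnan(m).any():
        raise InputError(f"{path}: non-numeric entries in LD matrix")
    if (m < 0).any() or (m > 1).any():
        raise InputError(f"{path}: r2 outside [0,1]")
    if not np.allclose(m, m.T, atol=1e-8):
        raise InputError(f"{path}: LD matrix asymmetric beyond 1e-8")
    return LdMatrix(labels, m)


def _looks_square(raw: pd.DataFrame) -> bool:
    # a 3x3 (or smaller) square matrix with labels also has 3 columns after
    # the index; treat it as square when header and first column agree
    first_col = [str(v) for v in raw.iloc[:, 0]]
    header_rest = [str(c) for c in raw.columns[1:]]
    return len(first_col) == len(header_rest) and first_col == header_rest


# ---------------------------------------------------------------------------
# results


def _sig6(x: object) -> str:
    if x is None:
        return "NA"
    try:
        xf = float(x)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return str(x)
    if math.isnan(xf):
        return "NA"
    return f"{xf:.6g}"


def write_results(results: Sequence, path: str) -> None:
    """Write MR results as a TSV with a fixed column order.

    One row per :class:`~wbcmr.estimators.MrResult`; floats are serialized
    with 6 significant digits, absent diagnostics as ``NA``.
    """
    if not results:
        raise ValueError("write_results requires a non-empty results collection")
    buf = io.StringIO()
    buf.write("\t".join(RESULT_COLUMNS) + "\n")
    for r in results:
        row = [
            getattr(r, "exposure", "") or "",
            getattr(r, "outcome", "") or "",
            getattr(r, "direction", "") or "",
            r.method,
            str(int(r.n_snps)),
            _sig6(r.estimate), _sig6(r.se), _sig6(r.ci_low), _sig6(r.ci_high),
            _sig6(r.pvalue), _sig6(getattr(r, "fdr_q", None)),
            _sig6(getattr(r, "q_stat", None)),
            _sig6(getattr(r, "egger_intercept", None)),
            _sig6(getattr(r, "egger_intercept_p", None)),
        ]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results(path: str) -> pd.DataFrame:
    """Read a results TSV produced by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
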
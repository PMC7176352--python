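"""Instrument selection and exposure/outcome allele harmonization.

The selection cascade mirrors the study design for genetically
instrumenting blood-cell counts: keep SNPs at genome-wide significance
(P < 8.31e-9 in the exposure GWAS) that are common (MAF > 5%), discard
strand-ambiguous palindromic SNPs with MAF > 40%, discard the MHC region
(chr6:20-40 Mb, GRCh37, densely pleiotropic), then LD-prune to pairwise
r² < 0.2. Harmonization aligns the outcome effect onto the exposure's
effect allele, flipping its sign for allele swaps and recognising strand
complements; unresolvable records are dropped with a log entry, never
guessed. The reverse-direction analysis reuses the same cascade with a
P < 5e-8 threshold.

MAF filtering uses the exposure GWAS frequencies (the frequencies travel
with the exposure records); records with missing frequency pass the MAF
filter but are conservatively dropped at the palindrome stage when
strand-ambiguous, because their orientation cannot be resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wbcmr.sumstats_io import LdMatrix, SumstatsTable

logger = logging.getLogger("wbcmr.instruments")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: genome-wide significance threshold of the blood-cell exposure GWAS
GENOME_WIDE_CELL = 8.31e-9
#: conventional genome-wide threshold used for the reverse (BP-instrument) scan
GENOME_WIDE_BP = 5e-8
#: MHC region, GRCh37
MHC_REGION = ("6", 20_000_000, 40_000_000)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing the instrument-selection cascade."""

    pvalue_threshold: float = GENOME_WIDE_CELL
    maf_min: float = 0.05
    palindrome_maf_max: float = 0.40
    r2_threshold: float = 0.2
    excluded_regions: tuple[tuple[str, int, int], ...] = (MHC_REGION,)

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue_threshold < 1.0:
            raise ValueError("pvalue_threshold must lie in (0,1)")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0,0.5)")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in (0,1]")
        # normalize chromosome labels to bare strings ("6", "X")
        regions = tuple((str(c).removeprefix("chr"), int(a), int(b))
                        for c, a, b in self.excluded_regions)
        object.__setattr__(self, "excluded_regions", regions)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects aligned to one effect allele."""

    rsid: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float = float("nan")
    flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_x > 0 or not self.se_y > 0:
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


def _maf(eaf: pd.Series) -> pd.Series:
    return np.minimum(eaf, 1.0 - eaf)


def filter_significant(exposure: SumstatsTable, cfg: SelectionConfig) -> SumstatsTable:
    """Keep records at genome-wide significance with MAF above the floor.

    Strictly ``pvalue < cfg.pvalue_threshold`` and ``MAF > cfg.maf_min``;
    records with unknown frequency pass the MAF clause here (they are dealt
    with at the palindrome stage). Order is preserved.
    """
    df = exposure.df
    maf = _maf(df["eaf"])
    keep = (df["pvalue"] < cfg.pvalue_threshold) & ((maf > cfg.maf_min) | maf.isna())
    out = exposure.subset(keep.to_numpy())
    if len(out) == 0:
        logger.warning("%s: no SNP passed p<%g with MAF>%g",
                       exposure.trait_name, cfg.pvalue_threshold, cfg.maf_min)
    logger.info("%s: significance+MAF filter kept %d/%d",
                exposure.trait_name, len(out), len(exposure))
    return out


def exclude_palindromic(table: SumstatsTable, cfg: SelectionConfig) -> SumstatsTable:
    """Drop strand-ambiguous (A/T, C/G) SNPs whose MAF exceeds the bound.

    Palindromic SNPs with unknown frequency are also dropped: without a
    frequency their strand cannot even in principle be resolved.
    """
    df = table.df
    pal = (
        ((df["effect_allele"] == "A") & (df["other_allele"] == "T"))
        | ((df["effect_allele"] == "T") & (df["other_allele"] == "A"))
        | ((df["effect_allele"] == "C") & (df["other_allele"] == "G"))
        | ((df["effect_allele"] == "G") & (df["other_allele"] == "C"))
    )
    maf = _maf(df["eaf"])
    drop = pal & ((maf > cfg.palindrome_maf_max) | maf.isna())
    out = table.subset(~drop.to_numpy())
    logger.info("%s: palindrome filter dropped %d", table.trait_name, int(drop.sum()))
    return out


def exclude_regions(table: SumstatsTable, cfg: SelectionConfig) -> SumstatsTable:
    """Drop SNPs inside any configured closed genomic interval (e.g. the MHC)."""
    df = table.df
    chrom = df["chrom"].astype(str).str.removeprefix("chr")
    drop = pd.Series(False, index=df.index)
    for c, start, end in cfg.excluded_regions:
        drop |= (chrom == c) & (df["pos"] >= start) & (df["pos"] <= end)
    out = table.subset(~drop.to_numpy())
    logger.info("%s: region filter dropped %d", table.trait_name, int(drop.sum()))
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = str(chrom).removeprefix("chr")
    try:
        return (int(c), "")
    except ValueError:
        return (10**6, c)


def ld_prune(table: SumstatsTable, ld: LdMatrix, cfg: SelectionConfig) -> SumstatsTable:
    """Greedy LD pruning: best p-value first, accept while r² < threshold.

    Candidates are visited by ascending p-value (ties broken by chromosome,
    position, then rsid, so the result is deterministic); a candidate is
    accepted iff its r² with every already-accepted SNP is strictly below
    ``cfg.r2_threshold``. Pairs absent from the LD panel count as r²=0
    (logged). Output keeps the input row order.
    """
    df = table.df
    known = set(ld.rsids)
    n_unknown = sum(r not in known for r in df["rsid"])
    if n_unknown:
        logger.info("%s: %d rsids absent from LD panel, treated as unlinked",
                    table.trait_name, n_unknown)
    order = sorted(
        df.index,
        key=lambda i: (df.at[i, "pvalue"], _chrom_sort_key(df.at[i, "chrom"]),
                       df.at[i, "pos"], df.at[i, "rsid"]),
    )
    accepted: list[str] = []
    accepted_idx: set[int] = set()
    for i in order:
        rsid = df.at[i, "rsid"]
        if all(ld.lookup(rsid, kept) < cfg.r2_threshold for kept in accepted):
            accepted.append(rsid)
            accepted_idx.add(i)
    keep = df.index.isin(accepted_idx)
    out = table.subset(keep)
    logger.info("%s: LD pruning kept %d/%d", table.trait_name, len(out), len(table))
    return out


def select_instruments(exposure: SumstatsTable, ld: LdMatrix,
                       cfg: SelectionConfig | None = None) -> SumstatsTable:
    """Full cascade: significance+MAF -> palindrome -> region -> LD pruning."""
    cfg = cfg or SelectionConfig()
    t = filter_significant(exposure, cfg)
    t = exclude_palindromic(t, cfg)
    t = exclude_regions(t, cfg)
    t = ld_prune(t, ld, cfg)
    return t


def harmonize(instruments: SumstatsTable, outcome: SumstatsTable) -> list[HarmonizedInstrument]:
    """Align outcome effects onto each instrument's exposure effect allele.

    For every instrument rsid present in the outcome GWAS the allele pairs
    are compared: identical pairs copy the outcome beta; swapped pairs negate
    it; pairs matching after strand complement (A<->T, C<->G), with or
    without a swap, behave the same after complementing. Instruments absent
    from the outcome, or with irreconcilable alleles, are dropped with a log
    entry. Output order follows the instrument table. ``|beta_y|`` and
    ``se_y`` are never altered — only the sign of ``beta_y``.
    """
    out_map = {row["rsid"]: row for row in outcome.df.to_dict("records")}
    harmonized: list[HarmonizedInstrument] = []
    n_absent = n_mismatch = 0
    for row in instruments.df.to_dict("records"):
        o = out_map.get(row["rsid"])
        if o is None:
            n_absent += 1
            continue
        ea, oa = row["effect_allele"], row["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        # precedence: exact identity, exact swap, then strand complements —
        # so palindromic pairs resolve by allele identity alone
        if (o_ea, o_oa) == (ea, oa):
            beta_y, flipped = o["beta"], False
        elif (o_ea, o_oa) == (oa, ea):
            beta_y, flipped = -o["beta"], True
        elif (c_ea, c_oa) == (ea, oa):
            beta_y, flipped = o["beta"], False
        elif (c_ea, c_oa) == (oa, ea):
            beta_y, flipped = -o["beta"], True
        else:
            n_mismatch += 1
            logger.info("harmonize: %s alleles %s/%s vs %s/%s irreconcilable, dropped",
                        row["rsid"], ea, oa, o_ea, o_oa)
            continue
        harmonized.append(HarmonizedInstrument(
            rsid=row["rsid"], beta_x=row["beta"], se_x=row["se"],
            beta_y=beta_y, se_y=o["se"], eaf=row["eaf"], flipped=flipped))
    if n_absent or n_mismatch:
        logger.info("harmonize: %d absent from outcome, %d allele mismatches dropped",
                    n_absent, n_mismatch)
    return harmonized
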
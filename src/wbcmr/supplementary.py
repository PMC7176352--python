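"""Re-analysis of published per-SNP instrument tables.

Published MR studies ship their instrument sets as supplementary tables:
one row per SNP with the allele pair and the effect (beta, SE) on the
exposure and on the outcome. Given such a table this module re-runs the
estimators on exactly the published instruments — the cheapest possible
replication, since it needs no access to the full GWAS scans.

Expected layout (TSV, or .xlsx read through openpyxl): columns
``rsid, ea, oa, eaf, beta_exposure, se_exposure, beta_outcome,
se_outcome`` (remappable via ``column_map``). Effects must refer to the
same effect allele ``ea``; tables exported from harmonization tools
already satisfy this.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from wbcmr.estimators import MrResult, ivw, scale_estimate
from wbcmr.instruments import HarmonizedInstrument

logger = logging.getLogger("wbcmr.supplementary")

IV_COLUMNS = {
    "rsid": "rsid",
    "eaf": "eaf",
    "beta_exposure": "beta_exposure",
    "se_exposure": "se_exposure",
    "beta_outcome": "beta_outcome",
    "se_outcome": "se_outcome",
}


def load_iv_table(path: str, column_map: Mapping[str, str] | None = None,
                  sheet: str | int = 0) -> list[HarmonizedInstrument]:
    """Read a published instrument table into harmonized instruments."""
    colmap = dict(IV_COLUMNS)
    if column_map:
        colmap.update(column_map)
    if str(path).endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in colmap.values() if c not in df.columns and c != "eaf"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(HarmonizedInstrument(
            rsid=str(row[colmap["rsid"]]),
            beta_x=float(row[colmap["beta_exposure"]]),
            se_x=float(row[colmap["se_exposure"]]),
            beta_y=float(row[colmap["beta_outcome"]]),
            se_y=float(row[colmap["se_outcome"]]),
            eaf=float(row[colmap["eaf"]]) if colmap["eaf"] in df.columns else float("nan"),
        ))
    logger.info("%s: %d instruments loaded", path, len(out))
    return out


def reproduce_published_ivw(path: str, sd_outcome: float = 1.0,
                            column_map: Mapping[str, str] | None = None,
                            sheet: str | int = 0) -> MrResult:
    """Random-effects IVW on a published instrument table.

    ``sd_outcome`` rescales the estimate from the outcome GWAS's raw units
    to SD units when the published numbers are SD-scaled (pass 1.0 for
    effects already on the printed scale, e.g. mm Hg per SD of exposure).
    """
    h = load_iv_table(path, column_map=column_map, sheet=sheet)
    return scale_estimate(ivw(h), sd_outcome)
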
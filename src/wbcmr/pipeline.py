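"""Orchestration: forward and reverse MR across exposure-outcome pairs.

For every exposure-outcome pair the pipeline selects instruments from the
exposure scan (significance + MAF, palindrome, MHC-region and LD filters),
harmonizes them against the outcome scan, runs the four estimators plus
leave-one-out, and pools the p-values into Benjamini-Hochberg q-values
per method within the run direction. The reverse direction swaps the
roles of the two trait families and relaxes the significance threshold to
the conventional genome-wide 5e-8 used for the blood-pressure instrument
set. Pairs with too few usable instruments are skipped with a logged
reason and never abort the run; a fixed configuration and seed reproduce
every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from wbcmr import estimators as est
from wbcmr.estimators import LooTable, MrResult, PressoDiagnostics, EstimationError
from wbcmr.instruments import (GENOME_WIDE_BP, SelectionConfig, harmonize,
                               select_instruments)
from wbcmr.sumstats_io import (LdMatrix, SumstatsTable, read_ld, read_sumstats,
                               write_results)

logger = logging.getLogger("wbcmr.pipeline")

METHOD_ORDER = ("IVW", "Egger", "WeightedMedian", "PRESSO_raw", "PRESSO_corrected")


@dataclass
class RunConfig:
    """Declarative description of one bidirectional MR run."""

    exposures: list[tuple[str, str]]          # (trait name, sumstats path)
    outcomes: list[tuple[str, str]]
    seed: int
    direction: str = "forward"                # forward | reverse | both
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    reverse_selection: SelectionConfig = field(
        default_factory=lambda: SelectionConfig(pvalue_threshold=GENOME_WIDE_BP))
    ld_paths: dict[str, str] = field(default_factory=dict)
    column_map: dict[str, str] = field(default_factory=dict)
    n_boot: int = 1000
    n_sim: int = 1000
    outlier_alpha: float = 0.05
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("need at least one exposure and one outcome")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError("direction must be forward|reverse|both")
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sel = SelectionConfig(**raw.get("selection", {}))
        rev_raw = dict(raw.get("reverse_selection", {}))
        rev_raw.setdefault("pvalue_threshold", GENOME_WIDE_BP)
        rev = SelectionConfig(**rev_raw)
        settings = raw.get("estimators", {})
        return cls(
            exposures=[(e["name"], e["path"]) for e in raw["exposures"]],
            outcomes=[(o["name"], o["path"]) for o in raw["outcomes"]],
            seed=int(raw["seed"]),
            direction=raw.get("direction", "forward"),
            selection=sel, reverse_selection=rev,
            ld_paths={k: v for k, v in raw.get("ld", {}).items()},
            column_map=raw.get("column_map", {}),
            n_boot=int(settings.get("n_boot", 1000)),
            n_sim=int(settings.get("n_sim", 1000)),
            outlier_alpha=float(settings.get("outlier_alpha", 0.05)),
            fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Everything one run produced, keyed by (exposure, outcome, direction)."""

    results: list[MrResult]
    loo: dict[tuple[str, str, str], LooTable]
    presso: dict[tuple[str, str, str], PressoDiagnostics]
    instrument_counts: dict[tuple[str, str, str], int]
    skipped: list[dict]
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "exposure": r.exposure, "outcome": r.outcome,
                "direction": r.direction, "method": r.method,
                "n_snps": r.n_snps, "estimate": r.estimate, "se": r.se,
                "ci_low": r.ci_low, "ci_high": r.ci_high, "pvalue": r.pvalue,
                "fdr_q": r.fdr_q, "Q": r.q_stat,
                "egger_intercept": r.egger_intercept,
                "egger_intercept_p": r.egger_intercept_p,
            })
        return pd.DataFrame(rows)

    def save(self, out_dir: str) -> None:
        """Write results.tsv, per-pair leave-one-out TSVs and provenance.json.

        Outputs carry no wall-clock timestamps, so re-running an identical
        configuration reproduces every file byte for byte.
        """
        os.makedirs(out_dir, exist_ok=True)
        write_results(self.results, os.path.join(out_dir, "results.tsv"))
        for (exp, out, direction), loo in sorted(self.loo.items()):
            fname = f"loo_{direction}_{exp}_{out}.tsv".replace(" ", "_")
            loo.rows.to_csv(os.path.join(out_dir, fname), sep="\t", index=False,
                            float_format="%.6g")
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values, returned in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _pair_seed(base_seed: int, direction: str, idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, 0 if direction == "forward" else 1, idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def analyse_pair(exposure: SumstatsTable, outcome: SumstatsTable,
                 ld: LdMatrix, selection: SelectionConfig, *,
                 direction: str = "forward", seed: int = 0,
                 n_boot: int = 1000, n_sim: int = 1000,
                 outlier_alpha: float = 0.05):
    """Select, harmonize and estimate for one exposure-outcome pair.

    Returns ``(results, loo, presso_diag, n_instruments)``; estimators whose
    minimum instrument count is not met are skipped with a log entry.
    Raises :class:`EstimationError` when fewer than 2 instruments survive.
    """
    selected = select_instruments(exposure, ld, selection)
    h = harmonize(selected, outcome)
    n_inst = len(h)
    if n_inst < 2:
        raise EstimationError(
            f"{exposure.trait_name}->{outcome.trait_name}: only {n_inst} usable "
            "instruments after selection and harmonization")

    results: list[MrResult] = []
    loo = None
    diag = None

    results.append(est.ivw(h))
    try:
        results.append(est.egger(h))
    except EstimationError as e:
        logger.warning("egger skipped: %s", e)
    try:
        results.append(est.weighted_median(h, n_boot=n_boot, seed=seed))
    except EstimationError as e:
        logger.warning("weighted median skipped: %s", e)
    try:
        raw, corrected, diag = est.mr_presso(h, n_sim=n_sim, seed=seed + 1,
                                             outlier_alpha=outlier_alpha)
        results.append(raw)
        if corrected is not None:
            results.append(corrected)
    except EstimationError as e:
        logger.warning("MR-PRESSO skipped: %s", e)
    try:
        loo = est.leave_one_out(h)
    except EstimationError as e:
        logger.warning("leave-one-out skipped: %s", e)

    for r in results:
        r.exposure = exposure.trait_name
        r.outcome = outcome.trait_name
        r.direction = direction
    return results, loo, diag, n_inst


def _run_direction(exposure_tables, outcome_tables, ld_map, selection, *,
                   direction: str, cfg: RunConfig):
    results: list[MrResult] = []
    loo: dict = {}
    presso: dict = {}
    counts: dict = {}
    skipped: list[dict] = []
    idx = 0
    for exp in exposure_tables:
        ld = ld_map.get(exp.trait_name) or LdMatrix.identity(exp.rsids)
        for out in outcome_tables:
            seed = _pair_seed(cfg.seed, direction, idx)
            idx += 1
            key = (exp.trait_name, out.trait_name, direction)
            try:
                r, l, d, n_inst = analyse_pair(
                    exp, out, ld, selection, direction=direction, seed=seed,
                    n_boot=cfg.n_boot, n_sim=cfg.n_sim,
                    outlier_alpha=cfg.outlier_alpha)
            except EstimationError as e:
                logger.warning("pair skipped: %s", e)
                skipped.append({"exposure": exp.trait_name,
                                "outcome": out.trait_name,
                                "direction": direction, "reason": str(e)})
                continue
            results.extend(r)
            if l is not None:
                loo[key] = l
            if d is not None:
                presso[key] = d
            counts[key] = n_inst

    # BH within direction, separately per method
    for method in METHOD_ORDER:
        group = [r for r in results if r.method == method]
        if group:
            qs = fdr_adjust([r.pvalue for r in group])
            for r, q in zip(group, qs):
                r.fdr_q = float(q)
    return results, loo, presso, counts, skipped


def run_mr_tables(exposure_tables: Sequence[SumstatsTable],
                  outcome_tables: Sequence[SumstatsTable],
                  ld_map: Mapping[str, LdMatrix],
                  cfg: RunConfig) -> ResultsBundle:
    """Run the configured directions on already-loaded tables."""
    results: list[MrResult] = []
    loo: dict = {}
    presso: dict = {}
    counts: dict = {}
    skipped: list[dict] = []

    if cfg.direction in ("forward", "both"):
        r, l, p, c, s = _run_direction(exposure_tables, outcome_tables, ld_map,
                                       cfg.selection, direction="forward", cfg=cfg)
        results += r; loo |= l; presso |= p; counts |= c; skipped += s
    if cfg.direction in ("reverse", "both"):
        # roles swap: the former outcomes are instrumented at the BP threshold
        r, l, p, c, s = _run_direction(outcome_tables, exposure_tables, ld_map,
                                       cfg.reverse_selection, direction="reverse",
                                       cfg=cfg)
        results += r; loo |= l; presso |= p; counts |= c; skipped += s

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "direction": cfg.direction,
        "instrument_counts": {" -> ".join(k): v for k, v in sorted(counts.items())},
        "skipped": skipped,
        "n_results": len(results),
    }
    return ResultsBundle(results=results, loo=loo, presso=presso,
                         instrument_counts=counts, skipped=skipped,
                         provenance=provenance)


def run_mr(cfg: RunConfig) -> ResultsBundle:
    """Load the configured files and run the forward (and/or reverse) MR."""
    exposures = [read_sumstats(path, column_map=cfg.column_map or None,
                               trait_name=name)
                 for name, path in cfg.exposures]
    outcomes = [read_sumstats(path, column_map=cfg.column_map or None,
                              trait_name=name)
                for name, path in cfg.outcomes]
    ld_map = {name: read_ld(path) for name, path in cfg.ld_paths.items()}
    return run_mr_tables(exposures, outcomes, ld_map, cfg)


def run_reverse(cfg: RunConfig) -> ResultsBundle:
    """Run only the reverse direction of a configuration."""
    return run_mr(dataclasses.replace(cfg, direction="reverse"))


def export_snp_effects(h, path: str) -> None:
    """Per-SNP harmonized effects as TSV, for external scatter/forest plots."""
    rows = [{"rsid": i.rsid, "beta_x": i.beta_x, "se_x": i.se_x,
             "beta_y": i.beta_y, "se_y": i.se_y, "eaf": i.eaf,
             "flipped": i.flipped} for i in h]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
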
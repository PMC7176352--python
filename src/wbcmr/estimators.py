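"""Two-sample MR estimators built from per-SNP summary effects.

Given harmonized per-SNP exposure effects (beta_x, se_x) and outcome
effects (beta_y, se_y), the per-SNP Wald ratio b_j = beta_y_j / beta_x_j
estimates the causal effect under the instrumental-variable assumptions.
This module combines the ratios four ways:

* **IVW** — inverse-variance weighted mean of the Wald ratios, equivalent
  to origin-constrained weighted least squares of beta_y on beta_x. A
  multiplicative random-effects scale ``max(1, sqrt(Q/(J-1)))`` inflates
  the fixed-effect SE when Cochran's Q exceeds its degrees of freedom, so
  heterogeneity widens but never narrows the interval.
* **MR-Egger** — weighted regression of beta_y on beta_x with a free
  intercept; the intercept estimates average directional pleiotropy and the
  slope a pleiotropy-adjusted causal effect (valid under the InSIDE
  assumption). Inference is on t with J-2 degrees of freedom.
* **Weighted median** — the 50% weighted quantile of the ratio estimates;
  consistent while valid instruments carry a majority of the weight. Its SE
  comes from a parametric bootstrap of the ratios.
* **MR-PRESSO** — simulation-based residual-sum-of-squares test for
  horizontal pleiotropy with per-SNP outlier flagging, an outlier-corrected
  IVW estimate, and a distortion test comparing raw and corrected slopes.

Wald-ratio SEs use the first-order delta approximation se_y/|beta_x| by
default; a second-order option adds the exposure-uncertainty term.
All empirical p-values use the add-one rule (never exactly zero) and all
randomness flows through an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from wbcmr.instruments import HarmonizedInstrument

logger = logging.getLogger("wbcmr.estimators")


class EstimationError(ValueError):
    """Too few usable instruments, or a degenerate configuration."""


@dataclass
class MrResult:
    """One estimator's causal estimate with uncertainty and diagnostics."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    # pipeline annotations
    exposure: str | None = None
    outcome: str | None = None
    direction: str | None = None
    fdr_q: float | None = None


@dataclass
class PressoDiagnostics:
    """MR-PRESSO global, outlier and distortion test output."""

    global_rss: float
    global_p: float
    outlier_pvalues: dict[str, float]
    outlier_rsids: list[str]
    distortion_p: float
    n_sim: int
    seed: int


@dataclass
class LooTable:
    """Leave-one-out IVW estimates, one row per excluded SNP."""

    rows: pd.DataFrame  # rsid, estimate_without, se_without, pvalue_without, flagged
    full: MrResult


def _arrays(h: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_x for i in h], dtype=float)
    sx = np.array([i.se_x for i in h], dtype=float)
    by = np.array([i.beta_y for i in h], dtype=float)
    sy = np.array([i.se_y for i in h], dtype=float)
    rsids = [i.rsid for i in h]
    return rsids, bx, sx, by, sy


def ratio_estimates(h: Sequence[HarmonizedInstrument],
                    second_order: bool = False):
    """Per-SNP Wald ratios b_j = beta_y/beta_x with delta-method SEs.

    First order: s_j = se_y/|beta_x|. The second-order option adds the
    exposure-uncertainty term beta_y^2 * se_x^2 / beta_x^4 under the square
    root. SNPs with beta_x = 0 are dropped with a log entry.

    Returns ``(rsids, b, s)`` for the usable SNPs.
    """
    rsids, bx, sx, by, sy = _arrays(h)
    usable = bx != 0.0
    n_drop = int((~usable).sum())
    if n_drop:
        dropped = [r for r, u in zip(rsids, usable) if not u]
        logger.info("ratio_estimates: dropped %d SNPs with beta_x=0: %s",
                    n_drop, dropped[:5])
    if not usable.any():
        raise EstimationError("no usable SNP: all exposure effects are zero")
    bx, sx, by, sy = bx[usable], sx[usable], by[usable], sy[usable]
    rsids = [r for r, u in zip(rsids, usable) if u]
    b = by / bx
    if second_order:
        s = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        s = sy / np.abs(bx)
    return rsids, b, s


Z975 = float(stats.norm.ppf(0.975))

_TINY = float(np.finfo(float).tiny)


def _two_sided_p(stat: float, dist_sf) -> float:
    """Two-sided p with an underflow floor, so downstream FDR stays in (0,1]."""
    return max(float(2.0 * dist_sf(abs(stat))), _TINY)


def _ivw_from_ratios(b: np.ndarray, s: np.ndarray):
    w = s**-2.0
    est = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - est) ** 2))
    scale = max(1.0, np.sqrt(q / (len(b) - 1))) if len(b) > 1 else 1.0
    se = se_fixed * scale
    return est, se, q


def ivw(h: Sequence[HarmonizedInstrument], second_order: bool = False) -> MrResult:
    """Inverse-variance weighted estimate with multiplicative random effects.

    With weights w_j = s_j^-2 on the Wald ratios: the point estimate is the
    weighted mean, Cochran's Q the weighted squared deviation from it, and
    the SE the fixed-effect SE inflated by ``max(1, sqrt(Q/(J-1)))``.
    Two-sided p and the 95% CI use the standard normal.
    """
    if len(h) < 2:
        raise EstimationError(
            "IVW needs >= 2 instruments; use the single Wald ratio directly for J=1")
    _, b, s = ratio_estimates(h, second_order=second_order)
    if len(b) < 2:
        raise EstimationError("fewer than 2 usable instruments after dropping beta_x=0")
    est, se, q = _ivw_from_ratios(b, s)
    p = _two_sided_p(est / se, stats.norm.sf)
    return MrResult("IVW", est, se, est - Z975 * se, est + Z975 * se, p,
                    n_snps=len(b), q_stat=q)


def egger(h: Sequence[HarmonizedInstrument]) -> MrResult:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    Each SNP is first oriented so beta_x >= 0 (both betas negated when
    beta_x < 0) — the intercept is only meaningful for a fixed exposure
    orientation. Weights are se_y^-2. Both SEs are inflated by the residual
    scale ``max(1, sqrt(RSS_w/(J-2)))``; p-values and the CI use t(J-2).
    """
    if len(h) < 3:
        raise EstimationError("MR-Egger needs >= 3 instruments")
    _, bx, sx, by, sy = _arrays(h)
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    w = sy**-2.0
    # weighted normal equations for [intercept, slope]
    sw = np.sum(w)
    swx = np.sum(w * bx)
    swxx = np.sum(w * bx * bx)
    swy = np.sum(w * by)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx**2
    if det <= 0 or not np.isfinite(det):
        raise EstimationError("degenerate design in MR-Egger (constant beta_x?)")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    dof = len(bx) - 2
    scale = max(1.0, np.sqrt(rss_w / dof))
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(swxx / det) * scale
    tq = float(stats.t.ppf(0.975, dof))
    p_slope = _two_sided_p(slope / se_slope, lambda z: stats.t.sf(z, dof))
    p_int = _two_sided_p(intercept / se_int, lambda z: stats.t.sf(z, dof))
    q = rss_w  # Rucker's Q': heterogeneity about the Egger fit
    return MrResult(
        "Egger", float(slope), float(se_slope),
        float(slope - tq * se_slope), float(slope + tq * se_slope), p_slope,
        n_snps=len(bx), q_stat=q,
        egger_intercept=float(intercept), egger_intercept_se=float(se_int),
        egger_intercept_p=p_int)


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    b_sorted = b[order]
    wn = w[order] / np.sum(w)
    mid = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, mid, b_sorted))


def weighted_median(h: Sequence[HarmonizedInstrument], n_boot: int = 1000,
                    seed: int = 0) -> MrResult:
    """Weighted median of the Wald ratios (valid with <50% invalid weight).

    The point estimate interpolates the weighted ratio distribution at the
    50% point with inverse-variance weights. The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples
    b_j* ~ Normal(b_j, s_j); p and CI are normal-based.
    """
    if len(h) < 3:
        raise EstimationError("weighted median needs >= 3 instruments")
    _, b, s = ratio_estimates(h)
    if len(b) < 3:
        raise EstimationError("fewer than 3 usable instruments after dropping beta_x=0")
    w = s**-2.0
    est = _weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bk = rng.normal(b, s)
        boots[k] = _weighted_median_point(bk, w)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        raise EstimationError("degenerate bootstrap: zero spread in resampled medians")
    p = _two_sided_p(est / se, stats.norm.sf)
    return MrResult("WeightedMedian", est, se, est - Z975 * se, est + Z975 * se,
                    p, n_snps=len(b))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-constrained WLS slopes of by on bx, per left-out SNP.

    Supports batched input: bx/by of shape (..., J) with weights (J,).
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(h: Sequence[HarmonizedInstrument], n_sim: int = 1000,
              seed: int = 0, outlier_alpha: float = 0.05,
              ) -> tuple[MrResult, MrResult | None, PressoDiagnostics]:
    """MR-PRESSO: global pleiotropy test, outlier flagging, corrected IVW.

    The observed residual sum of squares compares each SNP's outcome effect
    with the prediction of the leave-one-out IVW slope, weighted by
    se_y^-2. Its null distribution comes from ``n_sim`` parametric
    replicates drawn under those leave-one-out fits (both betas resampled),
    with the RSS recomputed from scratch — leave-one-out slopes included —
    on each replicate. Per-SNP residual terms are compared against their
    simulated distributions and Bonferroni-adjusted; flagged SNPs are
    removed for the corrected IVW estimate. The distortion test compares the
    observed relative change (corrected - raw)/|raw| against the changes
    produced by removing random same-size subsets.

    Returns ``(raw, corrected, diagnostics)``; ``corrected`` is None when
    every SNP is flagged. Empirical p-values use the add-one rule, so the
    smallest attainable p is 1/(n_sim+1).
    """
    if len(h) < 4:
        raise EstimationError("MR-PRESSO needs >= 4 instruments")
    rsids, bx, sx, by, sy = _arrays(h)
    h_used = list(h)
    if np.any(bx == 0):
        keep = bx != 0
        logger.info("mr_presso: dropping %d SNPs with beta_x=0", int((~keep).sum()))
        rsids = [r for r, k in zip(rsids, keep) if k]
        h_used = [x for x, k in zip(h_used, keep) if k]
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
        if len(bx) < 4:
            raise EstimationError("MR-PRESSO needs >= 4 usable instruments")
    J = len(bx)
    w = sy**-2.0
    rng = np.random.default_rng(seed)

    theta_loo = _loo_slopes(bx, by, w)  # shape (J,)
    obs_terms = w * (by - theta_loo * bx) ** 2
    obs_rss = float(np.sum(obs_terms))

    # parametric replicates under the leave-one-out fits
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    theta_star = _loo_slopes(bx_star, by_star, w)
    sim_terms = w * (by_star - theta_star * bx_star) ** 2  # (n_sim, J)
    sim_rss = np.sum(sim_terms, axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(sim_terms >= obs_terms, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(per_snp_p * J, 1.0)
    flagged = adj_p < outlier_alpha
    outlier_rsids = [r for r, f in zip(rsids, flagged) if f]
    outlier_pvalues = dict(zip(rsids, adj_p.astype(float)))

    raw = ivw(h_used)
    raw.method = "PRESSO_raw"

    corrected: MrResult | None = None
    distortion_p = float("nan")
    n_out = int(flagged.sum())
    if 0 < n_out < J - 1:
        kept = [x for x, f in zip(h_used, flagged) if not f]
        corrected = ivw(kept)
        corrected.method = "PRESSO_corrected"
        d_obs = (corrected.estimate - raw.estimate) / abs(raw.estimate)
        # null: remove random subsets of the same size
        d_null = np.empty(n_sim)
        b_all = by / bx
        w_ratio = (sy / np.abs(bx)) ** -2.0
        full_est = float(np.sum(w_ratio * b_all) / np.sum(w_ratio))
        for k in range(n_sim):
            drop = rng.choice(J, size=n_out, replace=False)
            keep_mask = np.ones(J, dtype=bool)
            keep_mask[drop] = False
            est_k = float(np.sum(w_ratio[keep_mask] * b_all[keep_mask])
                          / np.sum(w_ratio[keep_mask]))
            d_null[k] = (est_k - full_est) / abs(full_est)
        distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    elif n_out == 0:
        corrected = ivw(h_used)
        corrected.method = "PRESSO_corrected"
    else:
        logger.warning("mr_presso: %d/%d SNPs flagged; corrected estimate unavailable",
                       n_out, J)

    diag = PressoDiagnostics(
        global_rss=obs_rss, global_p=global_p,
        outlier_pvalues=outlier_pvalues, outlier_rsids=outlier_rsids,
        distortion_p=distortion_p, n_sim=n_sim, seed=seed)
    return raw, corrected, diag


def leave_one_out(h: Sequence[HarmonizedInstrument]) -> LooTable:
    """IVW recomputed excluding each SNP in turn.

    A row is flagged when excluding its SNP changes the sign of the estimate
    or moves the p-value across 0.05 relative to the full-set IVW — the
    signature of a single variant driving the association.
    """
    if len(h) < 3:
        raise EstimationError("leave-one-out needs >= 3 instruments")
    full = ivw(h)
    rows = []
    for j in range(len(h)):
        subset = [x for i, x in enumerate(h) if i != j]
        r = ivw(subset)
        flagged = (np.sign(r.estimate) != np.sign(full.estimate)) or (
            (r.pvalue < 0.05) != (full.pvalue < 0.05))
        rows.append({"rsid": h[j].rsid, "estimate_without": r.estimate,
                     "se_without": r.se, "pvalue_without": r.pvalue,
                     "flagged": bool(flagged)})
    return LooTable(rows=pd.DataFrame(rows), full=full)


def scale_estimate(r: MrResult, sd_outcome: float) -> MrResult:
    """Rescale an estimate from raw outcome units to SD units.

    Divides estimate, SE and CI by ``sd_outcome`` (e.g. the outcome trait's
    phenotypic SD); the p-value is scale-invariant and unchanged.
    """
    if not sd_outcome > 0:
        raise ValueError("sd_outcome must be > 0")
    return replace(r, estimate=r.estimate / sd_outcome, se=r.se / sd_outcome,
                   ci_low=r.ci_low / sd_outcome, ci_high=r.ci_high / sd_outcome)
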
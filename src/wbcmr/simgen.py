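"""Synthetic-data generators with known ground truth for both study stages.

``simulate_sumstats`` emulates a pair of GWAS summary-statistics tables —
an exposure scan (blood-cell count, UKB+INTERVAL-scale sample) and an
outcome scan (blood-pressure index, UKB+ICBP-scale sample) — for a set of
independent instruments with a known causal effect theta, configurable
horizontal pleiotropy, planted outliers, and correlated estimation errors
to mimic sample overlap between the two scans.

``simulate_cohort`` emulates a biobank-style cross-section: covariates,
correlated log-normal white-cell counts with a configurable zero mass
(basophils are not detected in a quarter of participants), a latent blood
pressure with planted per-quintile effects, antihypertensive-medication
use that increases with latent pressure and lowers the recorded readings,
duplicate readings with measurement error, and a fraction of missing
second readings.

Every draw flows from one explicit seed through numpy's SeedSequence
splitting, so identical configurations are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize

from wbcmr.sumstats_io import LdMatrix, SumstatsTable

logger = logging.getLogger("wbcmr.simgen")

#: sample sizes of the GWAS the generator is scaled to: the blood-cell
#: scan (UKB+INTERVAL) and the blood-pressure meta-analysis (UKB+ICBP)
N_CELL_GWAS = 173_480
N_BP_GWAS = 757_601

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

# non-palindromic allele pairs (effect, other)
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
               ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth and knobs of one simulated exposure/outcome GWAS pair."""

    theta: float = 0.0
    pleiotropy_mode: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    n_snps: int = 100
    n_exposure: int = N_CELL_GWAS
    n_outcome: int = N_BP_GWAS
    overlap_fraction: float = 0.0
    seed: int = 0
    # generation details
    sigma_gamma: float | None = None      # None -> derived from target_median_f
    target_median_f: float = 60.0
    n_outliers: int = 0
    outlier_offset_se: float = 10.0       # offset in units of the SNP's se_y
    avoid_palindromes: bool = True
    ld_block_size: int = 1                # 1 -> identity LD
    ld_block_r2: float = 0.0
    exposure_name: str = "sim_exposure"
    outcome_name: str = "sim_outcome"
    #: filled by the generator: rsid -> planted pleiotropic offset
    outlier_rsids: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0,1]")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ValueError("pleiotropy_fraction must lie in [0,1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ValueError("n_outliers must lie in [0, n_snps]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["outlier_rsids"] = {r: off for r, off in self.outlier_rsids}
        return json.dumps(d, indent=2, sort_keys=True)


def _default_sigma_gamma(truth: SimTruth) -> float:
    """Effect-size scale giving the requested median instrument F-statistic.

    With allele frequency f ~ U(0.05, 0.5) the typical per-allele SE at the
    exposure sample size is se = 1/sqrt(2 f (1-f) n); the median of
    (gamma/se)^2 for gamma ~ N(0, sigma^2) equals the target when
    sigma = sqrt(F_med) * se_typ / z_med with z_med = 0.6745 (the normal
    median absolute deviation factor).
    """
    # E[2 f (1-f)] for f ~ U(0.05, 0.5)
    e_het = 2 * (0.275 - (0.45**2 / 12 + 0.275**2))
    se_typ = 1.0 / np.sqrt(e_het * truth.n_exposure)
    return float(np.sqrt(truth.target_median_f) * se_typ / 0.6745)


def _assign_positions(n: int) -> tuple[list[str], list[int]]:
    # one SNP per megabase starting at 50 Mb, cycling chromosomes 1..22;
    # keeps every simulated SNP outside the chr6 MHC window
    chroms = [str((j % 22) + 1) for j in range(n)]
    pos = [50_000_000 + (j // 22) * 1_000_000 for j in range(n)]
    return chroms, pos


def simulate_sumstats(truth: SimTruth) -> tuple[SumstatsTable, SumstatsTable, LdMatrix, SimTruth]:
    """Draw a paired exposure/outcome GWAS with known causal structure.

    Per SNP j: frequency f_j ~ U(0.05, 0.5); true exposure effect
    gamma_j ~ N(0, sigma_gamma^2); pleiotropy alpha_j per mode ("balanced"
    is mean-zero, "directional" has mean alpha_mean, "inside_violating"
    correlates alpha with gamma at r = 0.5, breaking the InSIDE
    assumption); planted outliers add offsets of ``outlier_offset_se``
    times that SNP's se_y. The true outcome effect is
    theta * gamma_j + alpha_j + offset_j. Observed effects add estimation
    noise with SEs 1/sqrt(2 f (1-f) n) and cross-table error correlation
    equal to ``overlap_fraction``.

    Returns ``(exposure, outcome, ld, truth_out)`` where ``truth_out``
    echoes the input with the planted outlier rsids/offsets filled in.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 101]))
    J = truth.n_snps
    sigma_gamma = truth.sigma_gamma or _default_sigma_gamma(truth)

    f = rng.uniform(0.05, 0.5, size=J)
    gamma = rng.normal(0.0, sigma_gamma, size=J)

    # directional/balanced pleiotropy is expressed on the exposure-increasing
    # allele (sign(gamma) multiplies alpha), the convention under which an
    # Egger intercept recovers the mean direct effect; the InSIDE-violating
    # mode instead correlates the raw direct effect with gamma (r = 0.5)
    if truth.pleiotropy_mode == "none":
        alpha = np.zeros(J)
    elif truth.pleiotropy_mode == "balanced":
        alpha = np.sign(gamma) * rng.normal(0.0, truth.alpha_sd, size=J)
    elif truth.pleiotropy_mode == "directional":
        alpha = np.sign(gamma) * rng.normal(truth.alpha_mean, truth.alpha_sd, size=J)
    else:  # inside_violating
        r = 0.5
        z = rng.normal(0.0, 1.0, size=J)
        alpha = truth.alpha_mean + truth.alpha_sd * (
            r * gamma / sigma_gamma + np.sqrt(1 - r**2) * z)
    if truth.pleiotropy_fraction < 1.0 and truth.pleiotropy_mode != "none":
        carrier = rng.random(J) < truth.pleiotropy_fraction
        alpha = np.where(carrier, alpha, 0.0)

    se_x = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * truth.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * truth.n_outcome)

    rsids = [f"rs{j + 1:06d}" for j in range(J)]
    offsets = np.zeros(J)
    outlier_pairs: list[tuple[str, float]] = []
    if truth.n_outliers:
        which = rng.choice(J, size=truth.n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=truth.n_outliers)
        for idx, sgn in zip(which, signs):
            offsets[idx] = sgn * truth.outlier_offset_se * se_y[idx]
            outlier_pairs.append((rsids[idx], float(offsets[idx])))

    big_gamma = truth.theta * gamma + alpha + offsets

    rho = truth.overlap_fraction
    e_common = rng.normal(0.0, 1.0, size=J)
    e_x = np.sqrt(rho) * e_common + np.sqrt(1 - rho) * rng.normal(0.0, 1.0, size=J)
    e_y = np.sqrt(rho) * e_common + np.sqrt(1 - rho) * rng.normal(0.0, 1.0, size=J)
    beta_x = gamma + se_x * e_x
    beta_y = big_gamma + se_y * e_y

    p_x = 2.0 * stats.norm.sf(np.abs(beta_x) / se_x)
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y) / se_y)

    pairs = _SAFE_PAIRS if truth.avoid_palindromes else _SAFE_PAIRS + _PALINDROMIC_PAIRS
    allele_idx = rng.integers(0, len(pairs), size=J)
    ea = [pairs[i][0] for i in allele_idx]
    oa = [pairs[i][1] for i in allele_idx]
    chroms, pos = _assign_positions(J)

    def _table(name: str, beta, se, p, n) -> SumstatsTable:
        df = pd.DataFrame({
            "rsid": rsids, "chrom": chroms, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": f,
            "beta": beta, "se": se,
            "pvalue": np.clip(p, np.finfo(float).tiny, 1.0),
            "n": float(n),
        })
        return SumstatsTable(name, df)

    exposure = _table(truth.exposure_name, beta_x, se_x, p_x, truth.n_exposure)
    outcome = _table(truth.outcome_name, beta_y, se_y, p_y, truth.n_outcome)

    if truth.ld_block_size > 1 and truth.ld_block_r2 > 0:
        m = np.eye(J)
        for start in range(0, J, truth.ld_block_size):
            blk = slice(start, min(start + truth.ld_block_size, J))
            sub = np.full((blk.stop - blk.start,) * 2, truth.ld_block_r2)
            np.fill_diagonal(sub, 1.0)
            m[blk, blk] = sub
        ld = LdMatrix(rsids, m)
    else:
        ld = LdMatrix.identity(rsids)

    truth_out = dataclasses.replace(truth, sigma_gamma=sigma_gamma,
                                    outlier_rsids=tuple(outlier_pairs))
    return exposure, outcome, ld, truth_out


# ---------------------------------------------------------------------------
# cohort generator


CELL_TYPES = ("monocyte", "lymphocyte", "eosinophil", "neutrophil", "basophil")

#: log-scale location/scale of the cell-count distributions (10^9 cells/L);
#: chosen to land near typical adult reference medians
_DEFAULT_COUNT_LOGMEAN = {
    "monocyte": np.log(0.48), "lymphocyte": np.log(1.95),
    "eosinophil": np.log(0.17), "neutrophil": np.log(4.2),
    "basophil": np.log(0.03),
}
_DEFAULT_COUNT_LOGSD = {
    "monocyte": 0.35, "lymphocyte": 0.32, "eosinophil": 0.60,
    "neutrophil": 0.35, "basophil": 0.50,
}

#: planted 5th-vs-1st quintile differences divided by 4 (mm Hg per quintile
#: step): the SBP values mirror the observational contrasts the cohort is
#: meant to emulate; DBP effects are set to 60% of SBP
_DEFAULT_QUINTILE_STEP = {
    "neutrophil": {"sbp": 4.74 / 4, "dbp": 0.6 * 4.74 / 4},
    "monocyte": {"sbp": 2.33 / 4, "dbp": 0.6 * 2.33 / 4},
    "lymphocyte": {"sbp": 1.49 / 4, "dbp": 0.6 * 1.49 / 4},
    "basophil": {"sbp": 0.63 / 4, "dbp": 0.6 * 0.63 / 4},
    "eosinophil": {"sbp": -0.95 / 4, "dbp": -0.6 * 0.95 / 4},
}

SMOKING_LEVELS = ("never", "former", "current")
ALCOHOL_LEVELS = ("never", "special_occasions", "one_to_three_monthly",
                  "once_twice_weekly", "three_four_weekly", "daily")


@dataclass(frozen=True)
class CohortSimConfig:
    """Knobs of the synthetic biobank cohort."""

    n: int = 50_000
    seed: int = 0
    baseline: dict = field(default_factory=lambda: {"sbp": 138.0, "dbp": 82.0})
    age_effect: dict = field(default_factory=lambda: {"sbp": 0.55, "dbp": 0.20})
    age2_effect: dict = field(default_factory=lambda: {"sbp": 0.0, "dbp": -0.012})
    bmi_effect: dict = field(default_factory=lambda: {"sbp": 0.55, "dbp": 0.45})
    male_effect: dict = field(default_factory=lambda: {"sbp": 4.5, "dbp": 2.0})
    smoking_effect: dict = field(default_factory=lambda: {
        "sbp": (0.0, 0.6, 1.0), "dbp": (0.0, 0.4, 0.8)})
    alcohol_effect: dict = field(default_factory=lambda: {
        "sbp": (0.0, 0.3, 0.8, 1.4, 2.1, 3.0), "dbp": (0.0, 0.2, 0.5, 0.9, 1.4, 2.0)})
    salt_effect: dict = field(default_factory=lambda: {"sbp": 0.4, "dbp": 0.25})
    quintile_effects: dict = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEFAULT_QUINTILE_STEP.items()})
    residual_sd: dict = field(default_factory=lambda: {"sbp": 14.0, "dbp": 8.5})
    bp_residual_corr: float = 0.6
    measurement_sd: dict = field(default_factory=lambda: {"sbp": 3.0, "dbp": 2.5})
    missing_second_fraction: float = 0.092
    count_corr: float = 0.30
    count_logmean: dict = field(default_factory=lambda: dict(_DEFAULT_COUNT_LOGMEAN))
    count_logsd: dict = field(default_factory=lambda: dict(_DEFAULT_COUNT_LOGSD))
    zero_mass: dict = field(default_factory=lambda: {"basophil": 0.25})
    medicated_fraction: float = 0.21
    med_bp_slope: float = 1.5        # logit slope per SD of latent SBP
    treatment_effect: dict = field(default_factory=lambda: {"sbp": 15.0, "dbp": 10.0})

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError("n must be >= 100")
        for c, zm in self.zero_mass.items():
            if not 0.0 <= zm < 1.0:
                raise ValueError(f"zero_mass[{c}] must lie in [0,1)")
            if c not in CELL_TYPES:
                raise ValueError(f"unknown cell type {c!r}")
        if not 0.0 <= self.missing_second_fraction < 1.0:
            raise ValueError("missing_second_fraction must lie in [0,1)")
        if not 0.0 <= self.medicated_fraction < 1.0:
            raise ValueError("medicated_fraction must lie in [0,1)")


def _quintile_label_for_effect(values: np.ndarray) -> np.ndarray:
    # local copy of the tie-sharing quintile rule (see cohort.assign_quintiles);
    # used to plant effects on the same groups the analysis will recover
    qs = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    return 1 + np.sum(values[:, None] > qs[None, :], axis=1)


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort table plus a ground-truth record.

    The latent (untreated) blood pressure of individual i is
    baseline + covariate terms + planted per-quintile cell-count effects
    + correlated residual. Medication use is Bernoulli with probability
    increasing in latent systolic pressure (logistic link, intercept solved
    so the expected medicated fraction matches the config); medicated
    individuals' *recorded* readings are lowered by the treatment effect.
    Each recorded reading adds independent measurement error, and a
    configurable fraction of individuals lacks the second reading.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    n = cfg.n

    sex = np.where(rng.random(n) < 0.54, "F", "M")
    age = rng.uniform(37.0, 73.0, size=n)
    bmi = np.clip(rng.normal(27.4, 4.8, size=n), 15.0, None)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=(0.55, 0.35, 0.10))
    alcohol = rng.choice(ALCOHOL_LEVELS, size=n,
                         p=(0.08, 0.11, 0.11, 0.26, 0.23, 0.21))
    salt = rng.integers(0, 5, size=n)  # ordinal 0..4

    # correlated log-normal cell counts
    k = len(CELL_TYPES)
    corr = np.full((k, k), cfg.count_corr)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    counts = {}
    for i, cell in enumerate(CELL_TYPES):
        c = np.exp(cfg.count_logmean[cell] + cfg.count_logsd[cell] * z[:, i])
        zm = cfg.zero_mass.get(cell, 0.0)
        if zm > 0:
            # detection floor: the lowest zero_mass fraction reads as 0
            c = np.where(c <= np.quantile(c, zm), 0.0, c)
        counts[cell] = np.round(c, 2)

    age_c = age - 55.0
    bmi_c = bmi - 27.4
    smoking_idx = np.array([SMOKING_LEVELS.index(s) for s in smoking])
    alcohol_idx = np.array([ALCOHOL_LEVELS.index(a) for a in alcohol])

    latent = {}
    for bp in ("sbp", "dbp"):
        y = np.full(n, cfg.baseline[bp])
        y += cfg.age_effect[bp] * age_c + cfg.age2_effect[bp] * (age_c**2) / 10.0
        y += cfg.bmi_effect[bp] * bmi_c
        y += np.where(sex == "M", cfg.male_effect[bp], 0.0)
        y += np.asarray(cfg.smoking_effect[bp])[smoking_idx]
        y += np.asarray(cfg.alcohol_effect[bp])[alcohol_idx]
        y += cfg.salt_effect[bp] * salt
        for cell, eff in cfg.quintile_effects.items():
            step = eff.get(bp, 0.0)
            if step:
                q = _quintile_label_for_effect(counts[cell])
                y += step * (q - 1)
        latent[bp] = y

    # correlated residuals across the two indices
    rho = cfg.bp_residual_corr
    e0 = rng.normal(size=n)
    e1 = rng.normal(size=n)
    e2 = rng.normal(size=n)
    latent["sbp"] = latent["sbp"] + cfg.residual_sd["sbp"] * (
        np.sqrt(rho) * e0 + np.sqrt(1 - rho) * e1)
    latent["dbp"] = latent["dbp"] + cfg.residual_sd["dbp"] * (
        np.sqrt(rho) * e0 + np.sqrt(1 - rho) * e2)

    # medication probability rises with latent SBP; intercept solved so the
    # expected medicated fraction matches the config
    sd_lat = np.std(latent["sbp"])
    zbp = (latent["sbp"] - np.mean(latent["sbp"])) / (sd_lat if sd_lat > 0 else 1.0)
    if cfg.medicated_fraction > 0:
        def _mean_p(a: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(a + cfg.med_bp_slope * zbp)))))
        a_star = optimize.brentq(lambda a: _mean_p(a) - cfg.medicated_fraction, -20, 20)
        p_med = 1.0 / (1.0 + np.exp(-(a_star + cfg.med_bp_slope * zbp)))
        on_meds = rng.random(n) < p_med
    else:
        on_meds = np.zeros(n, dtype=bool)

    readings = {}
    for bp in ("sbp", "dbp"):
        treated = latent[bp] - np.where(on_meds, cfg.treatment_effect[bp], 0.0)
        r1 = treated + rng.normal(0.0, cfg.measurement_sd[bp], size=n)
        r2 = treated + rng.normal(0.0, cfg.measurement_sd[bp], size=n)
        readings[f"{bp}1"], readings[f"{bp}2"] = r1, r2

    if cfg.missing_second_fraction > 0:
        miss = rng.random(n) < cfg.missing_second_fraction
        for bp in ("sbp", "dbp"):
            readings[f"{bp}2"] = np.where(miss, np.nan, readings[f"{bp}2"])

    df = pd.DataFrame({
        "sbp1": readings["sbp1"], "sbp2": readings["sbp2"],
        "dbp1": readings["dbp1"], "dbp2": readings["dbp2"],
        "on_bp_meds": on_meds, "sex": sex, "age": age, "bmi": bmi,
        "smoking": smoking, "alcohol": alcohol, "salt": salt,
        **counts,
    })
    truth = {
        "quintile_effects": {c: dict(v) for c, v in cfg.quintile_effects.items()},
        "baseline": dict(cfg.baseline),
        "treatment_effect": dict(cfg.treatment_effect),
        "medicated_fraction_target": cfg.medicated_fraction,
        "n": n, "seed": cfg.seed,
    }
    return df, truth
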
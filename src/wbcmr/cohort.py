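"""Observational quintile analysis of cell counts against blood pressure.

The workflow mirrors large-biobank practice: average two seated readings
per blood-pressure index (individuals with a single reading are excluded),
add +15/+10 mm Hg to the systolic/diastolic pressure of participants on
antihypertensive medication, cut each cell count into empirical quintiles
(ties share a group, so a zero-inflated count like basophils produces an
oversized first group), and fit an ordinary linear model of the pressure
index on the quintile factor adjusted for sex, age, age squared, BMI,
smoking status and alcohol intake frequency. Quintile contrasts are
reported as estimated marginal means with a global ANOVA F-test and
Bonferroni-corrected pairwise differences (the multiplier is supplied by
the caller, e.g. 150 for 5 cell types x 3 indices x 10 contrasts).

Complete-case analysis throughout: rows missing any model variable are
dropped with a log entry.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from patsy import dmatrices, build_design_matrices

logger = logging.getLogger("wbcmr.cohort")

BP_INDICES = ("sbp", "dbp", "pp")
MED_ADJUSTMENT = {"sbp": 15.0, "dbp": 10.0}

#: covariate set of the default adjustment model
BASE_COVARIATES = ("sex", "age", "bmi", "smoking", "alcohol")

COHORT_COLUMNS = ["sbp1", "sbp2", "dbp1", "dbp2", "on_bp_meds", "sex", "age",
                  "bmi", "smoking", "alcohol"]


@dataclass
class EmmTable:
    """Quintile-level estimated marginal means with ANOVA and post-hoc tests."""

    emm: pd.DataFrame        # quintile, n, emm, se, ci_low, ci_high
    f_stat: float
    f_pvalue: float
    pairwise: pd.DataFrame   # q_a, q_b, diff, se, pvalue, pvalue_bonf
    bp_index: str
    cell_type: str
    n_used: int
    bonferroni_m: int


def derive_bp(cohort: pd.DataFrame, medication_adjust: bool = True) -> pd.DataFrame:
    """Average duplicate readings into SBP/DBP/PP columns.

    Rows whose second systolic or diastolic reading is missing are excluded.
    When ``medication_adjust`` is set, +15/+10 mm Hg is added to the
    averaged SBP/DBP of participants on blood-pressure-lowering medication
    (PP is recomputed from the adjusted values, so it gains +5).
    """
    needed = ["sbp1", "sbp2", "dbp1", "dbp2"]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks reading columns: {missing}")
    complete = cohort[needed].notna().all(axis=1)
    n_excl = int((~complete).sum())
    if n_excl:
        logger.info("derive_bp: excluded %d/%d individuals without both readings",
                    n_excl, len(cohort))
    df = cohort.loc[complete].copy()
    df["sbp"] = (df["sbp1"] + df["sbp2"]) / 2.0
    df["dbp"] = (df["dbp1"] + df["dbp2"]) / 2.0
    if medication_adjust:
        meds = df["on_bp_meds"].astype(bool)
        df.loc[meds, "sbp"] += MED_ADJUSTMENT["sbp"]
        df.loc[meds, "dbp"] += MED_ADJUSTMENT["dbp"]
    df["pp"] = df["sbp"] - df["dbp"]
    return df.reset_index(drop=True)


def quintile_boundaries(values: np.ndarray | pd.Series) -> np.ndarray:
    """The 20/40/60/80 empirical percentiles of ``values``."""
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 observations for quintiles")
    return np.quantile(v, [0.2, 0.4, 0.6, 0.8])


def assign_quintiles(values: np.ndarray | pd.Series,
                     boundaries: np.ndarray | None = None) -> np.ndarray:
    """Quintile labels 1..5 with ties sharing a group.

    An individual's label is 1 plus the number of boundary values its count
    strictly exceeds, so all individuals with an identical value land in
    the same group and groups can be unbalanced (a heavy zero mass collects
    in group 1). Passing precomputed ``boundaries`` freezes the cut points,
    e.g. for a medication-exclusion sensitivity refit.
    """
    v = np.asarray(values, dtype=float)
    if boundaries is None:
        if len(np.unique(v)) < 2:
            logger.warning("assign_quintiles: fewer than 2 distinct values; single group")
            return np.ones(len(v), dtype=int)
        boundaries = quintile_boundaries(v)
    b = np.asarray(boundaries, dtype=float)
    return (1 + np.sum(v[:, None] > b[None, :], axis=1)).astype(int)


def _complete_cases(df: pd.DataFrame, cols: list[str], context: str) -> pd.DataFrame:
    ok = df[cols].notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("%s: dropped %d incomplete cases", context, n_drop)
    return df.loc[ok]


def _covariate_terms(covariates: tuple[str, ...]) -> list[str]:
    terms = []
    for c in covariates:
        if c == "sex":
            terms.append("C(sex)")
        elif c == "age":
            terms += ["age", "I(age**2)"]
        elif c in ("smoking", "alcohol"):
            terms.append(f"C({c})")
        else:
            terms.append(c)
    return terms


def fit_emm(df: pd.DataFrame, cell_type: str, bp_index: str,
            extra_covariates: tuple[str, ...] = (),
            bonferroni_m: int = 10,
            quintile_col: str | None = None,
            covariates: tuple[str, ...] = BASE_COVARIATES,
            weights: str = "proportional") -> EmmTable:
    """Covariate-adjusted estimated marginal means per cell-count quintile.

    Fits ``bp ~ C(quintile) + sex + age + age^2 + bmi + C(smoking) +
    C(alcohol)`` (plus any ``extra_covariates``, e.g. ``("salt",)``) by OLS
    and reports, per quintile, the model prediction averaged over the
    observed covariate distribution: continuous covariates at their sample
    means, categorical ones weighted by observed proportions
    (``weights="proportional"``) or equally (``weights="equal"``). The
    global F-test addresses the joint null of no quintile differences;
    the 10 pairwise EMM differences carry Bonferroni-multiplied p-values
    with the caller-supplied multiplier.
    """
    if bp_index not in df.columns:
        raise ValueError(f"column {bp_index!r} absent — call derive_bp first")
    if weights not in ("proportional", "equal"):
        raise ValueError("weights must be 'proportional' or 'equal'")
    work = df.copy()
    if quintile_col is None:
        quintile_col = "_quintile"
        work[quintile_col] = assign_quintiles(work[cell_type].to_numpy())
    model_cols = [bp_index, quintile_col, *covariates, *extra_covariates]
    work = _complete_cases(work, model_cols, f"fit_emm[{cell_type}->{bp_index}]")
    n_used = len(work)

    terms = _covariate_terms(tuple(covariates) + tuple(extra_covariates))
    formula = f"{bp_index} ~ C({quintile_col})" + "".join(f" + {t}" for t in terms)
    y, X = dmatrices(formula, work, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[i] for i in range(X.shape[1])
                   if abs(r[i, i]) < 1e-8] if r.shape[0] >= X.shape[1] else list(X.columns)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    res = sm.OLS(y, X).fit()

    design_info = X.design_info
    levels = sorted(work[quintile_col].unique())

    def _avg_row(level) -> np.ndarray:
        grid = work.copy()
        grid[quintile_col] = level
        (mat,) = build_design_matrices([design_info], grid)
        m = np.asarray(mat)
        if weights == "proportional":
            return m.mean(axis=0)
        # equal weighting over joint categorical cells, continuous at means
        cats = [c for c in ("sex", "smoking", "alcohol") if c in covariates]
        if not cats:
            return m.mean(axis=0)
        key = grid[cats].astype(str).agg("|".join, axis=1).to_numpy()
        cell_means = pd.DataFrame(m).groupby(key).mean().to_numpy()
        return cell_means.mean(axis=0)

    params = res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    dof = res.df_resid
    tq = float(stats.t.ppf(0.975, dof))

    rows = []
    avg_rows = {}
    counts = work[quintile_col].value_counts()
    for q in levels:
        a = _avg_row(q)
        avg_rows[q] = a
        est = float(a @ params)
        se = float(np.sqrt(a @ cov @ a))
        rows.append({"quintile": int(q), "n": int(counts[q]), "emm": est, "se": se,
                     "ci_low": est - tq * se, "ci_high": est + tq * se})
    emm_df = pd.DataFrame(rows)

    # global F on the quintile factor
    q_terms = [c for c in X.columns if c.startswith(f"C({quintile_col})")]
    fres = res.f_test(np.eye(len(X.columns))[[X.columns.get_loc(c) for c in q_terms]])
    f_stat, f_p = float(fres.fvalue), float(fres.pvalue)

    pw = []
    for qa, qb in itertools.combinations(levels, 2):
        c = avg_rows[qb] - avg_rows[qa]
        diff = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        p = float(2.0 * stats.t.sf(abs(diff) / se, dof)) if se > 0 else float("nan")
        pw.append({"q_a": int(qa), "q_b": int(qb), "diff": diff, "se": se,
                   "pvalue": p, "pvalue_bonf": min(1.0, p * bonferroni_m)})
    pw_df = pd.DataFrame(pw)

    return EmmTable(emm=emm_df, f_stat=f_stat, f_pvalue=f_p, pairwise=pw_df,
                    bp_index=bp_index, cell_type=cell_type, n_used=n_used,
                    bonferroni_m=bonferroni_m)


def sensitivity_exclude_medicated(cohort: pd.DataFrame, cell_type: str,
                                  bp_index: str,
                                  boundaries: np.ndarray | None = None,
                                  extra_covariates: tuple[str, ...] = (),
                                  bonferroni_m: int = 10) -> EmmTable:
    """Refit after dropping medicated individuals, with frozen quintile cuts.

    Quintile boundaries must come from the full cohort (they are computed
    here from it when not supplied); the retained individuals keep the
    labels they had before the exclusion. Blood pressure enters unadjusted
    (no +15/+10), since everyone retained is untreated.
    """
    derived = derive_bp(cohort, medication_adjust=False)
    if boundaries is None:
        boundaries = quintile_boundaries(derived[cell_type].to_numpy())
    derived["_quintile"] = assign_quintiles(derived[cell_type].to_numpy(), boundaries)
    kept = derived.loc[~derived["on_bp_meds"].astype(bool)].copy()
    logger.info("sensitivity_exclude_medicated: %d/%d unmedicated individuals kept",
                len(kept), len(derived))
    return fit_emm(kept, cell_type, bp_index, extra_covariates=extra_covariates,
                   bonferroni_m=bonferroni_m, quintile_col="_quintile")


def write_emm(table: EmmTable, path: str) -> None:
    """Serialize an EmmTable as a TSV with a commented header block."""
    with open(path, "w") as fh:
        fh.write(f"# cell_type={table.cell_type}\tbp_index={table.bp_index}\t"
                 f"n={table.n_used}\tF={table.f_stat:.6g}\tF_p={table.f_pvalue:.6g}\t"
                 f"bonferroni_m={table.bonferroni_m}\n")
        table.emm.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write("# pairwise\n")
        table.pairwise.to_csv(fh, sep="\t", index=False, float_format="%.6g")
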
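# Methods

## Two-sample summary-statistics MR

The package analyses pairs of GWAS summary-statistics tables: an exposure
scan (a white-blood-cell count, measured in SD units of the count) and an
outcome scan (a blood-pressure index in mm Hg, or the roles reversed). The
causal parameter θ is the change in outcome per unit (typically 1 SD) of
genetically predicted exposure, identified under the instrumental-variable
assumptions: instruments associate with the exposure, share no confounder
with the outcome, and affect the outcome only through the exposure.
`scale_estimate` converts mm Hg effects to SD units when an outcome SD is
supplied; the SD is always an explicit input, never assumed.

### Instrument selection

Filters run in a fixed order — significance + MAF, palindrome exclusion,
region exclusion, LD pruning — each a pure contraction of the candidate
table, so attrition can be read off the structured log:

* `pvalue_threshold` — 8.31e-9 for cell-count scans (the multiple-trait-
  adjusted genome-wide level used for blood-cell GWAS), 5e-8 for the
  reverse, blood-pressure-instrumented direction.
* `maf_min` = 0.05 — common variants only; frequencies are taken from the
  exposure scan, the one whose instruments they define.
* `palindrome_maf_max` = 0.40 — A/T and C/G SNPs with minor-allele
  frequency above 40% cannot be strand-resolved reliably and are dropped;
  palindromic SNPs with unknown frequency are likewise dropped.
* `excluded_regions` — default chr6:20,000,000–40,000,000 (GRCh37), the
  MHC, excluded for dense pleiotropy. Closed interval on both ends.
* `r2_threshold` = 0.2, strict inequality. Pruning is greedy in ascending
  p-value with deterministic tie-breaking (chromosome, position, rsid);
  a candidate is kept iff its r² with every kept SNP is < 0.2. Greedy
  best-p-first is the standard clumping heuristic; it maximizes the
  significance of the retained set but is not guaranteed to maximize its
  size.

Harmonization aligns the outcome effect to the exposure's effect allele:
exact identity copies, exact swap negates, and strand complements (A↔T,
C↔G) are tried only after the exact matches, so palindromic pairs resolve
by allele identity alone. Anything else is dropped with a log entry — no
frequency-based inference is attempted.

### Estimators

All estimators consume first-order Wald ratios b_j = β_Yj/β_Xj,
s_j = σ_Yj/|β_Xj| (a `second_order` flag adds the exposure-variance term
β_Yj²σ_Xj²/β_Xj⁴; default off, matching common tool behaviour).

* **IVW** uses multiplicative random effects with the scale floored at 1:
  heterogeneity (Cochran's Q over J−1 df) can widen but never narrow the
  fixed-effect interval. Inference is normal; 95% CIs use z = 1.95996.
* **MR-Egger** orients SNPs to β_X ≥ 0, fits weighted least squares with a
  free intercept (weights σ_Y⁻²), floors the residual scale at 1, and uses
  t(J−2) for both slope and intercept. The intercept estimates the mean
  direct effect per exposure-increasing allele; the slope is consistent
  under InSIDE (instrument strength independent of direct effects).
* **Weighted median** interpolates the inverse-variance-weighted ratio
  distribution at the 50% point; its SE is the SD of the point estimate
  over `n_boot` (default 1000) parametric resamples b_j* ~ N(b_j, s_j)
  under an explicit seed. Normal-based p and CI. The point estimate is
  invariant to input order; the bootstrap SE depends on the seed only.
* **MR-PRESSO** computes each SNP's residual from the leave-one-out IVW
  slope, weighted by σ_Y⁻²; the global test compares the observed residual
  sum of squares against `n_sim` (default 1000) parametric replicates in
  which both betas are redrawn and the leave-one-out slopes are recomputed
  from scratch. Per-SNP empirical p-values are Bonferroni-multiplied by J;
  flagged SNPs are removed for the corrected IVW. The distortion test
  compares the observed relative change of the estimate against the
  distribution obtained by deleting random same-size subsets (a deletion
  null rather than the original bootstrap variant; both are accepted
  practice, the deletion null being simpler and seed-reproducible).
  Bonferroni flagging at α = 0.05 is attainable only when
  J/(n_sim+1) < α — at J = 50 that requires n_sim ≥ 1000, which is why
  1000 is the default and the validated setting.
* **Leave-one-out** recomputes IVW without each SNP and flags rows whose
  exclusion changes the estimate's sign or moves its p-value across 0.05 —
  the signature of a single driving variant, as when one locus (e.g. a
  pleiotropic hub such as *SH2B3*) carries a borderline association.

All empirical p-values use the add-one rule (smallest attainable value
1/(n_sim+1), never 0); analytic p-values are floored at the smallest
positive double so downstream FDR input stays in (0,1].

### Pipeline and multiple testing

`run_mr` crosses every exposure with every outcome, skips pairs with fewer
than two usable instruments (logged, never fatal), and attaches
Benjamini–Hochberg q-values computed per estimator within one run
direction — the family that matches reporting one asterisked heat map per
method. The family is a configuration choice, not a statistical necessity;
pooling across methods would be more conservative. BH itself is delegated
to `statsmodels.stats.multitest`. Per-pair seeds derive from the run seed
through `numpy.random.SeedSequence`, so a fixed configuration and seed
reproduce every output byte for byte; for the same reason the provenance
record contains the configuration hash and seed but no wall-clock
timestamps.

## Observational quintile stage

`derive_bp` averages two seated readings per index, excludes individuals
lacking the second reading, and adds +15/+10 mm Hg (SBP/DBP) for
participants on BP-lowering medication — the standard correction for
treated pressures; pulse pressure is recomputed afterwards, so it gains
+5. Quintiles are cut at the empirical 20/40/60/80 percentiles with ties
sharing a group: a zero-inflated count (basophils are undetectable in
roughly a quarter of adults) produces an oversized first group rather than
an arbitrary split of identical values, and labels are invariant to
monotone transforms of the count.

`fit_emm` fits OLS of the BP index on the quintile factor plus sex, age,
age², BMI, smoking (3 levels), alcohol intake frequency (6 levels), and
optionally salt intake, on complete cases (dropped cases are logged).
Estimated marginal means are model predictions averaged over the observed
covariate distribution — continuous covariates at sample means,
categorical cells at observed proportions (an `equal` weighting option
averages categorical cells equally; with no interactions the quintile
contrasts are identical under both). The global quintile F-test and all 10
pairwise contrasts use the model covariance; the Bonferroni multiplier is
supplied by the caller (150 when the full 5-cell-type × 3-index × 10-
contrast family is analysed). The medication-exclusion sensitivity refit
freezes the full-cohort quintile boundaries and uses unadjusted pressures.

## What the generators emulate — and what they do not

`simulate_sumstats` draws, per SNP: frequency f ~ U(0.05, 0.5); true
exposure effect γ ~ N(0, σ_γ²), with σ_γ by default set so the median
instrument F-statistic is ≈ 60 at the exposure sample size (173,480, the
UKB+INTERVAL blood-cell scan scale) — the strong-instrument regime of
modern blood-cell GWAS; outcome SEs at the 757,601-sample scale of the
UKB+ICBP pressure meta-analysis; true outcome effect θγ plus pleiotropy
and planted outlier offsets (expressed in multiples of that SNP's outcome
SE); and observed effects with estimation errors correlated across the two
tables at `overlap_fraction`, emulating shared samples. Directional and
balanced pleiotropy attach to the exposure-increasing allele (α multiplied
by sign(γ)); with symmetric γ, pleiotropy placed on an arbitrary allele
would average to zero after orientation and no method could — or should —
recover it. The InSIDE-violating mode instead correlates the raw direct
effect with γ (r = 0.5). LD is identity by default, optionally
block-structured; positions avoid the MHC so region filtering does not
silently interact with simulation tests. Selection on the simulated scan
itself (winner's curse) arises only when the pipeline's significance
filter is applied to the generated tables, which is exactly how the
pipeline tests run it.

Not emulated: real LD architecture, allele-frequency/effect-size coupling,
population stratification, and real trait scales. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under its stated assumptions, not the reproduction of any particular
biological estimate from real data.

`simulate_cohort` draws covariates from plausible biobank-like marginals,
correlated log-normal cell counts with configurable zero mass (default
25% for basophils), a latent pressure composed of baseline + covariate
terms + planted per-quintile-step effects + correlated SBP/DBP residuals,
medication use with probability logistic in latent SBP (intercept solved
so the expected medicated fraction matches the 21% target), recorded
readings lowered by the treatment effect (default 15/10 mm Hg, so the
standard correction is exact in expectation), duplicate readings with
measurement error, and a 9.2% missing-second-reading fraction. The default
planted quintile effects mirror the observational contrast pattern of
large biobank analyses (strongest for neutrophils, protective for
eosinophils); recovery tests plant a single effect so the target contrast
is identifiable rather than confounded by correlated counts — with
correlated counts and multiple planted effects, the marginal contrast of
one cell type deliberately absorbs its neighbours', as it does in real
observational data.

## Numerical and validation notes

* First-order IVW carries the known O(1/F) regression-dilution bias; at
  the default instrument strength it is ≈ 0.8% of θ. Calibration tests
  therefore check exact unbiasedness in the no-exposure-noise regime
  (where the estimator's NOME assumption holds) and the realistic regime
  against a 0.19–0.21 band for θ = 0.2.
* Problem sizes in the test and acceptance runs — 500 replicates for
  type-I/recovery sweeps, 20–30 replicates for robustness and
  outlier-sensitivity ensembles, n = 50,000 for the cohort recovery,
  n_sim = n_boot = 1000 for single analyses — were chosen to keep
  Monte-Carlo error well below the tested tolerances while the whole suite
  runs in well under a minute of simulation time.
* Degenerate inputs: β_X = 0 drops the SNP (ratio undefined); all-flagged
  MR-PRESSO returns diagnostics without a corrected estimate; fewer than
  2/3/4 usable instruments raise a typed estimation error naming the
  estimator's minimum; constant cell counts collapse to a single quintile
  with a warning; rank-deficient EMM designs raise an error naming the
  aliased columns.
* Re-analysis of published instrument tables (`wbcmr.supplementary`)
  expects effects already on a shared allele, the format of journal
  supplements exported from harmonization tools. It reproduces printed
  IVW numbers only as faithfully as the table itself reports the
  harmonized per-SNP effects.

## Known limitations

No multivariable MR, mode-based estimators, Steiger filtering, proxy-SNP
substitution, or frequency-based palindrome alignment; LD is a file input
(no remote panel lookups); quantile-regression and GAM sensitivity
analyses of the observational stage are out of scope. The FDR family and
EMM weighting conventions are documented choices that a replication from
another toolchain may legitimately make differently.
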
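import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import make_instruments, simulate_harmonized
from wbcmr.estimators import (EstimationError, egger, ivw, leave_one_out,
                              mr_presso, ratio_estimates, scale_estimate,
                              weighted_median)
from wbcmr.instruments import HarmonizedInstrument


class TestRatioEstimates:
    def test_direct_arithmetic(self):
        h = [HarmonizedInstrument("rs1", beta_x=0.1, se_x=0.01, beta_y=0.05, se_y=0.01)]
        _, b, s = ratio_estimates(h)
        assert b[0] == pytest.approx(0.5) and s[0] == pytest.approx(0.1)

    def test_negative_exposure_effect(self):
        h = [HarmonizedInstrument("rs1", beta_x=-0.1, se_x=0.01, beta_y=0.05, se_y=0.01)]
        _, b, s = ratio_estimates(h)
        assert b[0] == pytest.approx(-0.5) and s[0] == pytest.approx(0.1)

    def test_zero_exposure_effect_dropped(self):
        h = [HarmonizedInstrument("rs1", beta_x=0.0, se_x=0.01, beta_y=0.05, se_y=0.01),
             HarmonizedInstrument("rs2", beta_x=0.1, se_x=0.01, beta_y=0.05, se_y=0.01)]
        rsids, b, _ = ratio_estimates(h)
        assert rsids == ["rs2"] and len(b) == 1

    def test_all_zero_raises(self):
        h = [HarmonizedInstrument("rs1", beta_x=0.0, se_x=0.01, beta_y=0.05, se_y=0.01)]
        with pytest.raises(EstimationError):
            ratio_estimates(h)

    def test_second_order_se_larger(self):
        h = [HarmonizedInstrument("rs1", beta_x=0.1, se_x=0.05, beta_y=0.05, se_y=0.01)]
        _, _, s1 = ratio_estimates(h)
        _, _, s2 = ratio_estimates(h, second_order=True)
        assert s2[0] > s1[0]


class TestIvw:
    def test_hand_computed_example(self):
        # equal weights: estimate = mean(0.4,0.5,0.6) = 0.5,
        # Q = 100*(0.01 + 0 + 0.01) = 2.0
        h = make_instruments([0.4, 0.5, 0.6], [0.1, 0.1, 0.1])
        r = ivw(h)
        assert r.estimate == pytest.approx(0.5, abs=1e-12)
        assert r.q_stat == pytest.approx(2.0, abs=1e-10)

    def test_homogeneous_ratios_fixed_se(self):
        h = make_instruments([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        r = ivw(h)
        assert r.estimate == pytest.approx(0.3, abs=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-18)
        w = np.array([0.1, 0.2, 0.3]) ** -2.0
        assert r.se == pytest.approx(w.sum() ** -0.5)

    def test_wls_oracle_equivalence(self, rng):
        """IVW point estimate equals origin-constrained WLS with 1/se_y^2 weights."""
        for _ in range(50):
            J = rng.integers(2, 30)
            bx = rng.normal(0.05, 0.02, J)
            bx[bx == 0] = 0.01
            by = rng.normal(0.2 * bx, 0.01)
            sy = rng.uniform(0.005, 0.05, J)
            h = [HarmonizedInstrument(f"r{j}", beta_x=bx[j], se_x=0.001,
                                      beta_y=by[j], se_y=sy[j]) for j in range(J)]
            wls = sm.WLS(by, bx, weights=sy**-2.0).fit()
            assert ivw(h).estimate == pytest.approx(wls.params[0], abs=1e-10)

    def test_needs_two_instruments(self):
        with pytest.raises(EstimationError, match="Wald"):
            ivw(make_instruments([0.5], [0.1]))

    def test_ci_brackets_estimate(self, clean_instruments):
        r = ivw(clean_instruments[0])
        assert r.ci_low <= r.estimate <= r.ci_high


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11])
        a, th = 0.01, 0.3
        h = [HarmonizedInstrument(f"r{j}", beta_x=bx[j], se_x=1e-4,
                                  beta_y=a + th * bx[j], se_y=0.01)
             for j in range(4)]
        r = egger(h)
        assert r.egger_intercept == pytest.approx(a, abs=1e-10)
        assert r.estimate == pytest.approx(th, abs=1e-10)

    def test_orientation_invariance(self, clean_instruments):
        h, _ = clean_instruments
        flipped = list(h)
        f = flipped[3]
        flipped[3] = HarmonizedInstrument(f.rsid, beta_x=-f.beta_x, se_x=f.se_x,
                                          beta_y=-f.beta_y, se_y=f.se_y)
        r0, r1 = egger(h), egger(flipped)
        assert r1.estimate == pytest.approx(r0.estimate, abs=1e-12)
        assert r1.egger_intercept == pytest.approx(r0.egger_intercept, abs=1e-12)

    def test_statsmodels_wls_oracle(self, rng):
        for _ in range(20):
            J = rng.integers(4, 40)
            bx = np.abs(rng.normal(0.05, 0.02, J)) + 1e-3
            by = rng.normal(0.01 + 0.2 * bx, 0.02)
            sy = rng.uniform(0.005, 0.05, J)
            h = [HarmonizedInstrument(f"r{j}", beta_x=bx[j], se_x=0.001,
                                      beta_y=by[j], se_y=sy[j]) for j in range(J)]
            res = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
            r = egger(h)
            assert r.egger_intercept == pytest.approx(res.params[0], abs=1e-10)
            assert r.estimate == pytest.approx(res.params[1], abs=1e-10)
            # our SE applies a floor of 1 to the residual scale factor
            scale = np.sqrt(res.scale)
            expect_se = res.bse[1] / scale * max(1.0, scale)
            assert r.se == pytest.approx(expect_se, rel=1e-8)

    def test_directional_pleiotropy_recovered(self):
        h, _ = simulate_harmonized(theta=0.2, pleiotropy_mode="directional",
                                   alpha_mean=0.02, alpha_sd=0.01,
                                   n_snps=200, seed=11)
        r = egger(h)
        assert abs(r.egger_intercept - 0.02) < 3 * r.egger_intercept_se

    def test_intercept_type1_error_balanced(self):
        """Nominal 5% intercept test under mean-zero pleiotropy."""
        rejections = 0
        n_rep = 1000
        for s in range(n_rep):
            h, _ = simulate_harmonized(theta=0.2, pleiotropy_mode="balanced",
                                       alpha_sd=0.002, n_snps=100, seed=50_000 + s)
            rejections += egger(h).egger_intercept_p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_needs_three_instruments(self):
        with pytest.raises(EstimationError):
            egger(make_instruments([0.4, 0.5], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_is_ordinary_median(self):
        h = make_instruments([1.0, 2.0, 9.0], [0.1, 0.1, 0.1])
        assert weighted_median(h, seed=1).estimate == pytest.approx(2.0)

    def test_concentrated_weight_limit(self):
        h = make_instruments([1.0, 2.0, 9.0], [10.0, 1e-4, 10.0])
        assert weighted_median(h, seed=1).estimate == pytest.approx(2.0, abs=1e-6)

    def test_order_invariant_point_estimate(self, clean_instruments, rng):
        h, _ = clean_instruments
        shuffled = list(h)
        rng.shuffle(shuffled)
        assert (weighted_median(shuffled, seed=5).estimate
                == pytest.approx(weighted_median(h, seed=5).estimate, abs=1e-14))

    def test_robust_to_30pct_invalid(self):
        h, _ = simulate_harmonized(theta=0.2, pleiotropy_mode="directional",
                                   alpha_mean=0.03, alpha_sd=0.005,
                                   pleiotropy_fraction=0.3, n_snps=100, seed=42)
        wm = weighted_median(h, seed=7)
        iv = ivw(h)
        assert abs(wm.estimate - 0.2) < 3 * wm.se
        assert iv.estimate - 0.2 > 3 * iv.se

    def test_bit_reproducible(self, clean_instruments):
        h, _ = clean_instruments
        a = weighted_median(h, n_boot=200, seed=9)
        b = weighted_median(h, n_boot=200, seed=9)
        assert a.se == b.se and a.estimate == b.estimate


class TestPresso:
    def test_planted_outliers_recovered(self):
        # Bonferroni floors the adjusted p at J/(n_sim+1), so J=50 needs
        # n_sim=1000 for flagging at alpha=0.05 to be attainable at all.
        # Outlier offsets have random signs, so "corrected closer to truth"
        # is asserted on the ensemble, flagging on every replicate.
        raw_bias, corr_bias = [], []
        for seed in range(21, 31):
            h, truth = simulate_harmonized(theta=0.2, n_snps=50, n_outliers=2,
                                           outlier_offset_se=15, seed=seed)
            planted = {r for r, _ in truth.outlier_rsids}
            raw, corrected, diag = mr_presso(h, n_sim=1000, seed=3)
            assert planted <= set(diag.outlier_rsids)
            raw_bias.append(abs(raw.estimate - 0.2))
            corr_bias.append(abs(corrected.estimate - 0.2))
        assert np.mean(corr_bias) < np.mean(raw_bias)

    def test_add_one_rule_floor(self):
        # an extreme outlier makes the observed RSS unreachable by simulation
        h, _ = simulate_harmonized(theta=0.2, n_snps=8, n_outliers=1,
                                   outlier_offset_se=60, seed=4)
        _, _, diag = mr_presso(h, n_sim=200, seed=5)
        assert diag.global_p == pytest.approx(1 / 201)
        assert all(p >= 1 / 201 for p in diag.outlier_pvalues.values())

    def test_clean_data_global_test_calm(self):
        calm = 0
        for s in range(20):
            h, _ = simulate_harmonized(theta=0.2, n_snps=50, seed=900 + s)
            _, _, diag = mr_presso(h, n_sim=300, seed=s)
            calm += diag.global_p > 0.05
        assert calm >= 18

    def test_bit_reproducible(self):
        h, _ = simulate_harmonized(theta=0.2, n_snps=20, seed=33)
        d1 = mr_presso(h, n_sim=200, seed=8)[2]
        d2 = mr_presso(h, n_sim=200, seed=8)[2]
        assert d1.global_p == d2.global_p
        assert d1.outlier_pvalues == d2.outlier_pvalues

    def test_needs_four_instruments(self):
        with pytest.raises(EstimationError):
            mr_presso(make_instruments([0.4, 0.5, 0.6], [0.1] * 3))


class TestLeaveOneOut:
    def test_homogeneous_rows_constant(self):
        h = make_instruments([0.3] * 5, [0.1] * 5)
        t = leave_one_out(h)
        np.testing.assert_allclose(t.rows["estimate_without"], 0.3, atol=1e-12)
        assert not t.rows["flagged"].any()

    def test_j3_equals_complement_ivw(self):
        h = make_instruments([0.2, 0.5, 0.9], [0.1, 0.05, 0.2])
        t = leave_one_out(h)
        for j in range(3):
            oracle = ivw([x for i, x in enumerate(h) if i != j])
            assert t.rows.loc[j, "estimate_without"] == pytest.approx(oracle.estimate)
            assert t.rows.loc[j, "se_without"] == pytest.approx(oracle.se)

    def test_dominant_outlier_flagged(self):
        # 11 concordant weak ratios plus one heavily-weighted discordant SNP:
        # only its exclusion flips both the sign and the significance
        h = make_instruments([0.05] * 11 + [-1.0], [0.1] * 11 + [0.03])
        t = leave_one_out(h)
        flagged = t.rows.loc[t.rows["flagged"], "rsid"].tolist()
        assert flagged == [h[-1].rsid]


class TestScaleEstimate:
    def test_identity_and_arithmetic(self, clean_instruments):
        r = ivw(clean_instruments[0])
        assert scale_estimate(r, 1.0).estimate == r.estimate
        scaled = scale_estimate(r, 20.0)
        assert scaled.estimate == pytest.approx(r.estimate / 20)
        assert scaled.pvalue == r.pvalue

    def test_round_trip(self, clean_instruments):
        r = ivw(clean_instruments[0])
        back = scale_estimate(scale_estimate(r, 20.0), 1 / 20.0)
        assert back.estimate == pytest.approx(r.estimate, abs=1e-12)
        assert back.se == pytest.approx(r.se, abs=1e-12)

    def test_rejects_nonpositive_sd(self, clean_instruments):
        r = ivw(clean_instruments[0])
        with pytest.raises(ValueError):
            scale_estimate(r, 0.0)


class TestEquivariance:
    def test_negating_outcome_negates_estimates(self, clean_instruments):
        h, _ = clean_instruments
        neg = [HarmonizedInstrument(i.rsid, beta_x=i.beta_x, se_x=i.se_x,
                                    beta_y=-i.beta_y, se_y=i.se_y) for i in h]
        assert ivw(neg).estimate == pytest.approx(-ivw(h).estimate, abs=1e-12)
        assert egger(neg).estimate == pytest.approx(-egger(h).estimate, abs=1e-12)
        assert (weighted_median(neg, seed=2).estimate
                == pytest.approx(-weighted_median(h, seed=2).estimate, abs=1e-12))

    def test_rescaling_outcome_se_keeps_ivw_point(self, clean_instruments):
        h, _ = clean_instruments
        scaled = [HarmonizedInstrument(i.rsid, beta_x=i.beta_x, se_x=i.se_x,
                                       beta_y=i.beta_y, se_y=3.0 * i.se_y) for i in h]
        assert ivw(scaled).estimate == pytest.approx(ivw(h).estimate, abs=1e-12)
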
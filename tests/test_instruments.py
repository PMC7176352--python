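import itertools

import numpy as np
import pytest

from conftest import make_table, simulate_harmonized
from wbcmr.instruments import (COMPLEMENT, SelectionConfig, exclude_palindromic,
                               exclude_regions, filter_significant, harmonize,
                               ld_prune, select_instruments)
from wbcmr.sumstats_io import LdMatrix

CFG = SelectionConfig()


class TestSignificanceFilter:
    def test_subthreshold_pvalue_excluded(self):
        t = make_table([{"rsid": "a", "pvalue": 1e-7}])
        assert len(filter_significant(t, CFG)) == 0

    def test_rare_variant_excluded(self):
        t = make_table([{"rsid": "a", "eaf": 0.04, "pvalue": 1e-10}])
        assert len(filter_significant(t, CFG)) == 0

    def test_strong_common_variant_retained(self):
        t = make_table([{"rsid": "a", "eaf": 0.30, "pvalue": 1e-10}])
        assert filter_significant(t, CFG).rsids == ["a"]

    def test_maf_uses_minor_allele(self):
        # eaf 0.97 -> MAF 0.03 < 0.05
        t = make_table([{"rsid": "a", "eaf": 0.97, "pvalue": 1e-10}])
        assert len(filter_significant(t, CFG)) == 0


class TestPalindromeFilter:
    def test_high_maf_palindrome_removed(self):
        t = make_table([{"rsid": "a", "effect_allele": "A", "other_allele": "T",
                         "eaf": 0.45}])
        assert len(exclude_palindromic(t, CFG)) == 0

    def test_low_maf_palindrome_retained(self):
        t = make_table([{"rsid": "a", "effect_allele": "A", "other_allele": "T",
                         "eaf": 0.10}])
        assert len(exclude_palindromic(t, CFG)) == 1

    def test_non_palindromic_untouched(self):
        t = make_table([{"rsid": "a", "effect_allele": "A", "other_allele": "G",
                         "eaf": 0.45}])
        assert len(exclude_palindromic(t, CFG)) == 1

    def test_unknown_frequency_palindrome_dropped(self):
        t = make_table([{"rsid": "a", "effect_allele": "C", "other_allele": "G",
                         "eaf": np.nan}])
        assert len(exclude_palindromic(t, CFG)) == 0


class TestRegionFilter:
    @pytest.mark.parametrize("chrom,pos,kept", [
        ("6", 25_000_000, False),
        ("6", 19_999_999, True),
        ("6", 20_000_000, False),   # closed interval
        ("6", 40_000_000, False),
        ("7", 25_000_000, True),
    ])
    def test_mhc_boundaries(self, chrom, pos, kept):
        t = make_table([{"rsid": "a", "chrom": chrom, "pos": pos}])
        assert len(exclude_regions(t, CFG)) == (1 if kept else 0)


class TestLdPrune:
    def test_stronger_snp_dominates(self):
        t = make_table([{"rsid": "s1", "pvalue": 1e-20},
                        {"rsid": "s2", "pvalue": 1e-10}])
        ld = LdMatrix(["s1", "s2"], np.array([[1, 0.5], [0.5, 1]]))
        assert ld_prune(t, ld, CFG).rsids == ["s1"]

    def test_independent_snps_all_kept(self):
        t = make_table([{"rsid": f"s{i}", "pvalue": 10.0**-(10 + i)} for i in range(3)])
        ld = LdMatrix.identity(["s0", "s1", "s2"])
        assert len(ld_prune(t, ld, CFG)) == 3

    def test_chain_keeps_ends(self):
        # greedy on the 3-SNP chain (hand-enumerated): s1 accepted, s2 blocked
        # by r2=0.3 with s1, s3 accepted since r2(s1,s3)=0
        t = make_table([{"rsid": "s1", "pvalue": 1e-30},
                        {"rsid": "s2", "pvalue": 1e-20},
                        {"rsid": "s3", "pvalue": 1e-10}])
        m = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.3], [0.0, 0.3, 1.0]])
        ld = LdMatrix(["s1", "s2", "s3"], m)
        assert ld_prune(t, ld, CFG).rsids == ["s1", "s3"]

    def test_output_pairwise_r2_below_threshold(self, rng):
        n = 30
        a = rng.uniform(0, 1, size=(n, n))
        m = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(m, 1.0)
        rsids = [f"s{i}" for i in range(n)]
        t = make_table([{"rsid": r, "pvalue": float(p), "pos": 10**6 + i}
                        for i, (r, p) in enumerate(zip(rsids, rng.uniform(1e-30, 1e-9, n)))])
        ld = LdMatrix(rsids, m)
        kept = ld_prune(t, ld, CFG).rsids
        assert set(kept) <= set(rsids)
        for a_, b_ in itertools.combinations(kept, 2):
            assert ld.lookup(a_, b_) < CFG.r2_threshold

    def test_missing_from_panel_treated_unlinked(self):
        t = make_table([{"rsid": "s1", "pvalue": 1e-20},
                        {"rsid": "zz", "pvalue": 1e-10}])
        ld = LdMatrix.identity(["s1"])
        assert len(ld_prune(t, ld, CFG)) == 2


def _oracle_align(exp_pair, out_pair):
    """Independent truth table: returns sign multiplier or None (drop)."""
    ea, oa = exp_pair
    flip = {"A": "T", "T": "A", "C": "G", "G": "C"}
    o_ea, o_oa = out_pair
    if (o_ea, o_oa) == (ea, oa):
        return +1
    if (o_ea, o_oa) == (oa, ea):
        return -1
    if (flip[o_ea], flip[o_oa]) == (ea, oa):
        return +1
    if (flip[o_ea], flip[o_oa]) == (oa, ea):
        return -1
    return None


class TestHarmonize:
    def test_identity_swap_complement(self):
        exp = make_table([{"rsid": "a", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.1}])
        for out_alleles, expected in [(("A", "G"), 0.05), (("G", "A"), -0.05),
                                      (("T", "C"), 0.05), (("C", "T"), -0.05)]:
            out = make_table([{"rsid": "a", "effect_allele": out_alleles[0],
                               "other_allele": out_alleles[1], "beta": 0.05}])
            h = harmonize(exp, out)
            assert len(h) == 1
            assert h[0].beta_y == pytest.approx(expected)
            assert h[0].flipped == (expected < 0)

    def test_full_allele_enumeration(self):
        """Exhaustive cross-check against an independent truth-table oracle."""
        bases = "ACGT"
        pairs = [(a, b) for a in bases for b in bases if a != b]
        for exp_pair in pairs:
            exp = make_table([{"rsid": "x", "effect_allele": exp_pair[0],
                               "other_allele": exp_pair[1], "beta": 0.1}])
            for out_pair in pairs:
                out = make_table([{"rsid": "x", "effect_allele": out_pair[0],
                                   "other_allele": out_pair[1], "beta": 0.05}])
                h = harmonize(exp, out)
                want = _oracle_align(exp_pair, out_pair)
                if want is None:
                    assert h == []
                else:
                    assert len(h) == 1
                    assert h[0].beta_y == pytest.approx(want * 0.05)

    def test_absent_rsid_dropped(self):
        exp = make_table([{"rsid": "a"}, {"rsid": "b"}])
        out = make_table([{"rsid": "a", "beta": 0.02}])
        h = harmonize(exp, out)
        assert [i.rsid for i in h] == ["a"]

    def test_magnitudes_never_change(self):
        h, _ = simulate_harmonized(theta=0.1, n_snps=40, seed=3,
                                   avoid_palindromes=False)
        for inst in h:
            assert inst.se_y > 0 and inst.se_x > 0


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(99)
    n = 80
    bases = "ACGT"
    rows = []
    for i in range(n):
        ea, oa = rng.choice(list(bases), size=2, replace=False)
        rows.append({
            "rsid": f"s{i}", "chrom": str(rng.integers(1, 9)),
            "pos": int(rng.integers(1, 60_000_000)),
            "effect_allele": ea, "other_allele": oa,
            "eaf": float(rng.uniform(0, 1)),
            "pvalue": float(10.0 ** rng.uniform(-30, 0)),
        })
    return make_table(rows)


class TestFilterAlgebra:
    """The selection filters are contractions, idempotent, and commute."""

    FILTERS = [filter_significant, exclude_palindromic, exclude_regions]

    @pytest.mark.parametrize("f", FILTERS)
    def test_contraction_and_idempotence(self, f, random_table):
        once = f(random_table, CFG)
        assert set(once.rsids) <= set(random_table.rsids)
        assert f(once, CFG).rsids == once.rsids

    @pytest.mark.parametrize("f,g", list(itertools.permutations(FILTERS, 2)))
    def test_commutation(self, f, g, random_table):
        assert f(g(random_table, CFG), CFG).rsids == g(f(random_table, CFG), CFG).rsids

    def test_full_cascade_subset_of_input(self, random_table):
        ld = LdMatrix.identity(random_table.rsids)
        out = select_instruments(random_table, ld, CFG)
        assert set(out.rsids) <= set(random_table.rsids)
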
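"""LD statistics: r2, two-locus EM, distance bins, decay fit, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popstrat.ld import (
    LD_BINS_MBP,
    assign_bin,
    bin_ld,
    em_two_locus_freqs,
    fit_decay,
    ld_records,
    pair_r2,
    paired_interval_test,
    r2_from_freqs,
)


def haps_from_counts(n_ab, n_aB, n_Ab, n_ab_low):
    """Two haplotype columns realising given AB/Ab/aB/ab counts."""
    a = np.array([1] * n_ab + [1] * n_aB + [0] * n_Ab + [0] * n_ab_low)
    b = np.array([1] * n_ab + [0] * n_aB + [1] * n_Ab + [0] * n_ab_low)
    return a, b


class TestPairR2:
    def test_complete_ld_gives_one(self):
        a, b = haps_from_counts(10, 0, 0, 10)
        assert pair_r2(a, b) == pytest.approx(1.0)

    def test_equilibrium_cross_gives_zero(self):
        # all four haplotypes equally frequent: D = 0
        a, b = haps_from_counts(5, 5, 5, 5)
        assert pair_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_intermediate_value(self):
        # counts AB=40, Ab=10, aB=10, ab=40: p1=p2=0.5, D=0.4-0.25=0.15,
        # r2 = 0.15^2 / 0.5^4 = 0.36
        a, b = haps_from_counts(40, 10, 10, 40)
        assert pair_r2(a, b) == pytest.approx(0.36)

    def test_monomorphic_locus_flagged_nan(self):
        a = np.ones(20)
        b = np.array([0, 1] * 10)
        assert np.isnan(pair_r2(a, b))

    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_invariant_to_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        if a.std() == 0 or b.std() == 0:
            return
        r = pair_r2(a, b)
        assert 0.0 <= r <= 1.0
        assert pair_r2(b, a) == pytest.approx(r)
        assert pair_r2(1 - a, b) == pytest.approx(r)
        assert pair_r2(1 - a, 1 - b) == pytest.approx(r)


class TestEMTwoLocus:
    def test_no_double_heterozygotes_is_exact_counting(self):
        # genotypes with no (het, het) pair: haplotypes are determined
        ga = np.array([1, 1, -1, -1, 0, 1])
        gb = np.array([1, -1, -1, 1, 1, 0])
        freqs, n_iter, conv = em_two_locus_freqs(ga, gb)
        assert conv
        # oracle: resolve each animal's two haplotypes by direct enumeration
        # (unambiguous because no animal is heterozygous at both loci)
        hapA, hapB = [], []
        for x, y in zip(ga + 1, gb + 1):
            if x == 1 and y == 1:
                raise AssertionError("fixture must avoid double heterozygotes")
            hapA += [1, 1] if x == 2 else [0, 0] if x == 0 else [1, 0]
            hapB += [1, 1] if y == 2 else [0, 0] if y == 0 else [1, 0]
        count = np.zeros(4)
        for ha, hb in zip(hapA, hapB):
            count[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(ha, hb)]] += 1
        np.testing.assert_allclose(freqs, count / count.sum(), atol=1e-9)

    def test_independent_loci_fixed_point_is_product(self):
        rng = np.random.default_rng(4)
        ga = rng.choice([-1, 0, 1], size=4000, p=[0.36, 0.48, 0.16])
        gb = rng.choice([-1, 0, 1], size=4000, p=[0.25, 0.5, 0.25])
        freqs, _, conv = em_two_locus_freqs(ga, gb)
        assert conv
        pA = freqs[0] + freqs[1]
        pB = freqs[0] + freqs[2]
        assert freqs[0] == pytest.approx(pA * pB, abs=0.02)

    def test_em_r2_matches_phased_r2_on_collapsed_genotypes(self, small_dataset):
        hap = small_dataset.populations["PL"].haplotypes
        # adjacent SNP pair with real LD, collapsed to genotypes
        a_col, b_col = hap.haplotypes[:, 10], hap.haplotypes[:, 11]
        truth = pair_r2(a_col, b_col)
        ga = a_col[0::2] + a_col[1::2] - 1
        gb = b_col[0::2] + b_col[1::2] - 1
        freqs, _, conv = em_two_locus_freqs(ga, gb)
        assert conv
        assert r2_from_freqs(freqs) == pytest.approx(truth, abs=0.05)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        ga = rng.choice([-1, 0, 1], 100)
        gb = rng.choice([-1, 0, 1], 100)
        freqs, _, _ = em_two_locus_freqs(ga, gb)
        assert freqs.sum() == pytest.approx(1.0)


class TestBinning:
    def test_half_open_boundary_goes_to_upper_bin(self):
        assert assign_bin([25_000])[0] == 1  # 0.025 Mbp -> [0.025, 0.05)

    def test_last_interval_closed_at_five_mbp(self):
        assert assign_bin([5_000_000])[0] == len(LD_BINS_MBP) - 1
        assert assign_bin([5_000_001])[0] == -1

    def test_mean_r2_is_arithmetic_mean(self):
        recs = pd.DataFrame(
            {"snp_i": ["a", "b"], "snp_j": ["b", "c"], "chrom": "1",
             "distance_bp": [10_000, 20_000], "r2": [0.2, 0.4]}
        )
        bins = bin_ld(recs)
        assert bins.loc[0, "mean_r2"] == pytest.approx(0.3)
        assert bins.loc[0, "n_pairs"] == 2

    def test_pair_counts_partition_all_close_pairs(self, small_dataset):
        hap = small_dataset.populations["PL"].haplotypes
        recs = ld_records(hap)
        bins = bin_ld(recs)
        assert bins["n_pairs"].sum() == len(recs)
        # every same-chromosome pair within 5 Mbp appears once (none dropped:
        # simulated SNPs are polymorphic)
        expected = 0
        for c in np.unique(hap.chrom):
            pos = hap.pos_bp[hap.chrom == c]
            d = np.abs(pos[:, None] - pos[None, :])
            expected += int((np.triu(d, 1) > 0).sum() - (np.triu(d, 1) > 5e6).sum())
        assert len(recs) == expected


class TestDecayFit:
    def test_noiseless_curve_recovered_exactly(self):
        d = np.array([b[1] for b in LD_BINS_MBP])
        bins = pd.DataFrame(
            {"d_upper_mbp": d, "mean_r2": 0.05 + 0.03 / np.sqrt(d),
             "n_pairs": 10}
        )
        fit = fit_decay(bins)
        assert fit.alpha == pytest.approx(0.05, abs=1e-12)
        assert fit.beta == pytest.approx(0.03, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(6)
        d = np.array([b[1] for b in LD_BINS_MBP])
        y = 0.04 + 0.05 / np.sqrt(d) + rng.normal(0, 0.01, d.size)
        bins = pd.DataFrame({"d_upper_mbp": d, "mean_r2": y, "n_pairs": 5})
        fit = fit_decay(bins)
        x = 1 / np.sqrt(d)
        beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        alpha = y.mean() - beta * x.mean()
        assert fit.beta == pytest.approx(beta)
        assert fit.alpha == pytest.approx(alpha)

    def test_underdetermined_fit_raises(self):
        bins = pd.DataFrame(
            {"d_upper_mbp": [0.025, 0.05], "mean_r2": [0.3, 0.2], "n_pairs": 3}
        )
        with pytest.raises(ValueError):
            fit_decay(bins)

    def test_predicted_decrease_ratio_equals_beta_ratio(self):
        d = np.array([b[1] for b in LD_BINS_MBP])
        mk = lambda beta: fit_decay(
            pd.DataFrame({"d_upper_mbp": d, "mean_r2": 0.02 + beta / np.sqrt(d),
                          "n_pairs": 4})
        )
        fa, fb = mk(0.06), mk(0.035)
        d1, d2 = 0.025, 0.075
        dec_a = fa.predict(d1) - fa.predict(d2)
        dec_b = fb.predict(d1) - fb.predict(d2)
        assert dec_a / dec_b == pytest.approx(fa.beta / fb.beta)


class TestPairedIntervalTest:
    def _records(self, r2, dist=10_000):
        n = len(r2)
        return pd.DataFrame(
            {"snp_i": [f"s{i}" for i in range(n)],
             "snp_j": [f"s{i + 1}" for i in range(n)],
             "chrom": "1", "distance_bp": dist, "r2": r2}
        )

    def test_identical_populations_give_null_result(self):
        r = np.linspace(0.1, 0.5, 10)
        res = paired_interval_test(self._records(r), self._records(r.copy()),
                                   (0.0, 0.025))
        assert res["t"] == 0.0
        assert res["p"] == 1.0

    def test_constant_offset_is_degenerate_with_zero_p(self):
        r = np.full(8, 0.3)
        res = paired_interval_test(self._records(r + 0.05), self._records(r),
                                   (0.0, 0.025))
        assert res["degenerate"]
        assert res["p"] == 0.0
        assert res["t"] == np.inf

    def test_statistic_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.1, 0.6, 50)
        diff = rng.normal(0.05, 0.01, 50)
        res = paired_interval_test(self._records(base + diff), self._records(base),
                                   (0.0, 0.025))
        t_expect = diff.mean() / (diff.std(ddof=1) / np.sqrt(50))
        assert res["t"] == pytest.approx(t_expect)
        assert res["n_pairs"] == 50

    def test_too_few_shared_pairs_flagged_invalid(self):
        res = paired_interval_test(self._records([0.2]), self._records([0.3]),
                                   (0.0, 0.025))
        assert not res["valid"]
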
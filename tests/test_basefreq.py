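"""Pedigree A-inverse and gene-content BLUP base allele frequencies."""

import numpy as np
import pytest

from popstrat.basefreq import (
    BaseFreqSet,
    GeneContentModel,
    Pedigree,
    a_inverse,
    base_freq_agreement,
    base_freqs_for_panel,
    gene_content_blup,
)
from popstrat.simdata import SimConfig, simulate_dataset


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Oracle: numerator relationship matrix by the tabular method."""
    sire, dam = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (A[s, d] / 2.0 if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += A[j, s] / 2.0
            if d >= 0:
                a += A[j, d] / 2.0
            A[i, j] = A[j, i] = a
    return A


def random_two_generation_pedigree(rng, n_founders, n_offspring, genotyped="offspring"):
    """Founders plus offspring of distinct founder pairs (no inbreeding)."""
    ids = [f"f{i}" for i in range(n_founders)]
    sires = ["0"] * n_founders
    dams = ["0"] * n_founders
    for k in range(n_offspring):
        s, d = rng.choice(n_founders, size=2, replace=False)
        ids.append(f"o{k}")
        sires.append(f"f{s}")
        dams.append(f"f{d}")
    gt = np.zeros(len(ids), dtype=bool)
    if genotyped == "offspring":
        gt[n_founders:] = True
    elif genotyped == "all":
        gt[:] = True
    return Pedigree(ids, sires, dams, gt)


class TestAInverse:
    def test_unrelated_founders_give_identity(self):
        ped = Pedigree(["a", "b", "c"], ["0"] * 3, ["0"] * 3)
        np.testing.assert_allclose(a_inverse(ped).toarray(), np.eye(3))

    def test_trio_matches_dense_inversion_of_a(self):
        ped = Pedigree(["s", "d", "o"], ["0", "0", "s"], ["0", "0", "d"])
        Ainv = a_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv, np.linalg.inv(tabular_a(ped)), atol=1e-12)
        # textbook trio entries
        assert Ainv[2, 2] == pytest.approx(2.0)
        assert Ainv[2, 0] == pytest.approx(-1.0)
        assert Ainv[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_product_with_tabular_a_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_two_generation_pedigree(rng, 8, 12)
        A = tabular_a(ped)
        np.testing.assert_allclose(a_inverse(ped).toarray() @ A, np.eye(ped.n),
                                   atol=1e-10)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(["a", "b"], ["b", "a"], ["0", "0"])


class TestGeneContentBlup:
    def test_unrelated_genotyped_animals_reduce_to_sample_mean(self):
        ped = Pedigree([f"a{i}" for i in range(4)], ["0"] * 4, ["0"] * 4,
                       np.ones(4, dtype=bool))
        gc = np.array([0.0, 1.0, 2.0, 1.0])
        assert gene_content_blup(ped, gc, lam=0.01) == pytest.approx(0.5)

    def test_monomorphic_snp_gives_frequency_one(self):
        ped = Pedigree([f"a{i}" for i in range(5)], ["0"] * 5, ["0"] * 5,
                       np.ones(5, dtype=bool))
        assert gene_content_blup(ped, np.full(5, 2.0)) == pytest.approx(1.0)

    def test_matches_dense_mme_solve_on_two_generation_pedigree(self):
        # 30-animal pedigree with drift: oracle assembles the dense MME
        rng = np.random.default_rng(3)
        ped = random_two_generation_pedigree(rng, 10, 20)
        founder_gc = rng.binomial(2, 0.35, 10).astype(float)
        sire, dam = ped.parent_indices()
        gc = np.full(ped.n, np.nan)
        gc[:10] = founder_gc
        for i in range(10, ped.n):
            gc[i] = sum(rng.binomial(1, gc[p] / 2.0) for p in (sire[i], dam[i]))
        observed = np.where(ped.genotyped, gc, np.nan)
        lam = 0.01
        mu, u = GeneContentModel(ped, lam).solve(observed)

        z = ped.genotyped.astype(float)
        Ainv = np.linalg.inv(tabular_a(ped))
        C = np.zeros((ped.n + 1, ped.n + 1))
        C[0, 0] = z.sum()
        C[0, 1:] = z
        C[1:, 0] = z
        C[1:, 1:] = np.diag(z) + lam * Ainv
        rhs = np.zeros(ped.n + 1)
        rhs[0] = np.nansum(observed)
        rhs[1:] = np.where(ped.genotyped, observed, 0.0)
        expect = np.linalg.solve(C, rhs)
        assert mu == pytest.approx(expect[0], abs=1e-8)
        np.testing.assert_allclose(u, expect[1:], atol=1e-8)

    def test_large_lambda_ignores_pedigree(self):
        rng = np.random.default_rng(4)
        ped = random_two_generation_pedigree(rng, 6, 10)
        gc = np.full(ped.n, np.nan)
        gc[ped.genotyped] = rng.binomial(2, 0.4, int(ped.genotyped.sum()))
        p = gene_content_blup(ped, gc, lam=1e8)
        assert p == pytest.approx(np.nanmean(gc[ped.genotyped]) / 2.0, abs=1e-4)

    def test_clamped_to_unit_interval(self):
        ped = Pedigree(["a", "b"], ["0", "0"], ["0", "0"], np.ones(2, dtype=bool))
        assert 0.0 <= gene_content_blup(ped, np.array([2.0, 2.0])) <= 1.0

    def test_allele_relabeling_mirrors_frequency(self):
        rng = np.random.default_rng(5)
        ped = random_two_generation_pedigree(rng, 8, 15)
        gc = np.full(ped.n, np.nan)
        gc[ped.genotyped] = rng.binomial(2, 0.3, int(ped.genotyped.sum()))
        p = gene_content_blup(ped, gc)
        q = gene_content_blup(ped, np.where(np.isnan(gc), np.nan, 2.0 - gc))
        assert q == pytest.approx(1.0 - p, abs=1e-10)

    def test_recovers_founder_frequencies_on_simulated_pedigree(self):
        cfg = SimConfig(n_animals=120, n_snp=150, n_chrom=1, seed=21,
                        missing_rate=0.0)
        ds = simulate_dataset(cfg)
        d = ds.populations["PL"]
        est = base_freqs_for_panel(d.pedigree, d.genotypes)
        mae = np.abs(est.p_base - ds.truth.pop_freqs["PL"]).mean()
        assert mae < 0.05


class TestAgreement:
    def test_identical_sets(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 50)
        a = BaseFreqSet("PL", [f"s{i}" for i in range(50)], p)
        b = BaseFreqSet("DE", [f"s{i}" for i in range(50)], p.copy())
        res = base_freq_agreement(a, b)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["slope"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_flipped_orientation_antisymmetry(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 50)
        ids = [f"s{i}" for i in range(50)]
        res = base_freq_agreement(BaseFreqSet("PL", ids, p),
                                  BaseFreqSet("DE", ids, 1.0 - p))
        assert res["pearson_r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-1.0)

    def test_balding_nichols_draws_agree_against_brute_force(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.05, 0.95, 5000)
        f = 0.01
        draw = lambda: rng.beta(base * (1 - f) / f, (1 - base) * (1 - f) / f)
        pa, pb = draw(), draw()
        ids = [f"s{i}" for i in range(5000)]
        res = base_freq_agreement(BaseFreqSet("PL", ids, pa),
                                  BaseFreqSet("DE", ids, pb))
        assert res["pearson_r"] >= 0.95
        # brute-force correlation formula as the oracle
        r_bf = (((pa - pa.mean()) * (pb - pb.mean())).sum()
                / np.sqrt(((pa - pa.mean()) ** 2).sum()
                          * ((pb - pb.mean()) ** 2).sum()))
        assert res["pearson_r"] == pytest.approx(r_bf)

    def test_too_few_shared_snps_raises(self):
        a = BaseFreqSet("PL", ["s1", "s2"], np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            base_freq_agreement(a, a)
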
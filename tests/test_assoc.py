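import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyat.io import ExpressionTable, Gene, GeneModelSet, GenotypeMatrix, site_table
from polyat.assoc import (
    AssociationResult,
    at_pc1_correlation,
    candidate_interval,
    filter_expressed,
    kinship,
    ld_prune,
    ld_r2,
    lmm_scan,
    significant_loci,
)


def _geno_from(dosage, chrom="1A", start=100, spacing=100):
    n_acc, n_sites = dosage.shape
    pos = start + spacing * np.arange(n_sites)
    bases = ["A", "C"]
    sites = site_table([chrom] * n_sites, pos, ["A"] * n_sites, ["C"] * n_sites)
    return GenotypeMatrix([f"s{i}" for i in range(n_acc)], sites, dosage)


def _binary(rng, n_acc, n_sites, p=0.5):
    return rng.binomial(1, p, size=(n_acc, n_sites)).astype(float)


class TestLdR2:
    def test_identical_and_flipped_vectors(self):
        d = np.array([[0, 1], [0, 1], [1, 0], [1, 0.]])
        geno = _geno_from(d)
        assert ld_r2(geno, 0, 1) == pytest.approx(1.0)

    def test_null_expectation_about_one_over_n(self):
        rng = np.random.default_rng(0)
        n = 200
        geno = _geno_from(_binary(rng, n, 100))
        r2s = [ld_r2(geno, 2 * k, 2 * k + 1) for k in range(50)]
        assert np.mean(r2s) == pytest.approx(1 / n, abs=3 / n)

    def test_zero_variance_flagged(self):
        d = np.array([[0, 1], [0, 0], [0, 1.]])
        geno = _geno_from(d)
        assert np.isnan(ld_r2(geno, 0, 1))


class TestLdPrune:
    def test_independent_sites_untouched(self):
        rng = np.random.default_rng(1)
        geno = _geno_from(_binary(rng, 300, 60))
        kept = ld_prune(geno)
        assert len(kept) == 60

    def test_duplicate_site_removed_later_kept_earlier(self):
        rng = np.random.default_rng(2)
        d = _binary(rng, 100, 10)
        d[:, 7] = d[:, 3]  # duplicate
        geno = _geno_from(d)
        kept = ld_prune(geno)
        assert 3 in kept and 7 not in kept

    def test_no_remaining_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        base = _binary(rng, 80, 8)
        cols = [base[:, i // 4] for i in range(32)]  # blocks of highly-related sites
        d = np.array(cols).T
        flip = rng.random(d.shape) < 0.05
        d = np.abs(d - flip)
        geno = _geno_from(d)
        kept = ld_prune(geno, window=10, step=10, r2_max=0.3)
        pruned = geno.subset_sites(kept)
        for a in range(len(kept)):
            for b in range(a + 1, min(a + 10, len(kept))):
                r2 = ld_r2(pruned, a, b)
                assert not (r2 > 0.3)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        base = _binary(rng, 60, 10)
        cols = [base[:, i // 5] for i in range(50)]
        d = np.array(cols).T
        flip = rng.random(d.shape) < 0.1
        d = np.abs(d - flip)
        geno = _geno_from(d)
        kept = ld_prune(geno, window=20, step=20)
        again = ld_prune(geno.subset_sites(kept), window=20, step=20)
        assert len(again) == len(kept)


class TestKinship:
    def test_duplicated_accession(self):
        rng = np.random.default_rng(5)
        d = _binary(rng, 20, 200)
        d[1] = d[0]
        K = kinship(_geno_from(d))
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(6)
        K = kinship(_geno_from(_binary(rng, 30, 150)))
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_subpopulation_structure(self):
        rng = np.random.default_rng(7)
        p1 = rng.uniform(0.1, 0.9, 300)
        p2 = np.clip(p1 + rng.normal(0, 0.35, 300), 0.02, 0.98)
        d = np.vstack([rng.binomial(1, p1, size=(25, 300)),
                       rng.binomial(1, p2, size=(25, 300))]).astype(float)
        K = kinship(_geno_from(d))
        within = (K[:25, :25].sum() - np.trace(K[:25, :25])) / (25 * 24)
        between = K[:25, 25:].mean()
        assert within > between


class TestPc1Correlation:
    def test_phenotype_equal_to_pc1(self):
        rng = np.random.default_rng(8)
        d = _binary(rng, 30, 100)
        geno = _geno_from(d)
        dc = d - d.mean(axis=0)
        u, s, _ = np.linalg.svd(dc, full_matrices=False)
        pc1 = pd.Series(u[:, 0] * s[0], index=geno.accessions)
        assert at_pc1_correlation(geno, pc1) == pytest.approx(1.0)

    def test_independent_noise_small(self):
        rng = np.random.default_rng(9)
        geno = _geno_from(_binary(rng, 100, 300))
        noise = pd.Series(rng.normal(size=100), index=geno.accessions)
        assert at_pc1_correlation(geno, noise) < 0.35

    def test_group_linked_phenotype(self):
        """Two-population structure with a group-linked phenotype puts the
        phenotype on PC1 (|r| > 0.9)."""
        rng = np.random.default_rng(10)
        p1 = rng.uniform(0.1, 0.9, 400)
        p2 = np.clip(p1 + rng.normal(0, 0.4, 400), 0.02, 0.98)
        d = np.vstack([rng.binomial(1, p1, size=(30, 400)),
                       rng.binomial(1, p2, size=(30, 400))]).astype(float)
        geno = _geno_from(d)
        y = pd.Series(np.r_[np.zeros(30), np.ones(30)] + rng.normal(0, 0.15, 60),
                      index=geno.accessions)
        assert at_pc1_correlation(geno, y) > 0.9


class TestLmmScan:
    def test_identity_kinship_equals_ols(self):
        """With K = I the mixed-model scan collapses to per-marker OLS."""
        rng = np.random.default_rng(11)
        n, m = 40, 30
        d = _binary(rng, n, m)
        geno = _geno_from(d)
        y = pd.Series(rng.normal(size=n), index=geno.accessions)
        res = lmm_scan(geno, y, np.eye(n))
        for j in range(m):
            lr = stats.linregress(d[:, j], y.to_numpy())
            assert res.df["p"].iloc[j] == pytest.approx(lr.pvalue, abs=1e-8)
            assert res.df["beta"].iloc[j] == pytest.approx(lr.slope, abs=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        n, m = 30, 25
        d = _binary(rng, n, m)
        geno = _geno_from(d)
        K = kinship(geno)
        y = pd.Series(rng.normal(size=n), index=geno.accessions)
        res1 = lmm_scan(geno, y, K)
        perm = rng.permutation(n)
        accs = [geno.accessions[i] for i in perm]
        geno2 = GenotypeMatrix(accs, geno.sites, d[perm])
        res2 = lmm_scan(geno2, y.loc[accs], K[np.ix_(perm, perm)])
        np.testing.assert_allclose(res1.df["p"], res2.df["p"], rtol=1e-8)

    def test_monomorphic_marker_skipped(self):
        rng = np.random.default_rng(13)
        d = _binary(rng, 20, 5)
        d[:, 2] = 1.0
        geno = _geno_from(d)
        y = pd.Series(rng.normal(size=20), index=geno.accessions)
        res = lmm_scan(geno, y, np.eye(20))
        assert np.isnan(res.df["p"].iloc[2])
        assert res.m == 4

    def test_structured_null_is_calibrated(self):
        """Phenotype drawn from kinship-structured noise only: the scan's
        type-I error at alpha=0.05 stays near 0.05."""
        rejections = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            p1 = rng.uniform(0.1, 0.9, 200)
            p2 = np.clip(p1 + rng.normal(0, 0.3, 200), 0.02, 0.98)
            d = np.vstack([rng.binomial(1, p1, size=(30, 200)),
                           rng.binomial(1, p2, size=(30, 200))]).astype(float)
            geno = _geno_from(d)
            K = kinship(geno)
            L = np.linalg.cholesky(0.7 * K + 0.3001 * np.eye(60))
            y = pd.Series(L @ rng.normal(size=60), index=geno.accessions)
            res = lmm_scan(geno, y, K)
            rejections.append((res.df["p"].dropna() < 0.05).mean())
        assert 0.02 <= np.mean(rejections) <= 0.08


class TestLoci:
    def _result(self, chrom, pos, nlp):
        df = pd.DataFrame({"chrom": chrom, "pos": pos,
                           "beta": 0.0, "se": 1.0, "t": 0.0,
                           "p": 10.0 ** -np.asarray(nlp),
                           "neglog10p": nlp})
        return AssociationResult(df, 10, len(df), 1.0, 1.0, 1.0)

    def test_empty_when_nothing_passes(self):
        res = self._result(["1A"] * 3, [10, 20, 30], [1.0, 2.0, 5.9])
        assert significant_loci(res) == []

    def test_nearby_markers_merge(self):
        res = self._result(["1A"] * 2, [1000, 2000], [6.5, 7.5])
        loci = significant_loci(res)
        assert len(loci) == 1
        assert loci[0].peak_pos == 2000
        assert loci[0].n_markers == 2

    def test_two_chromosomes_two_loci(self):
        res = self._result(["1A", "7D"], [1000, 1000], [6.5, 8.0])
        loci = significant_loci(res)
        assert len(loci) == 2

    def test_distance_split(self):
        res = self._result(["1A"] * 2, [1_000_000, 9_000_000], [6.5, 7.0])
        assert len(significant_loci(res)) == 2


class TestCandidateInterval:
    def test_isolated_peak_single_position(self):
        rng = np.random.default_rng(14)
        d = _binary(rng, 200, 11)
        geno = _geno_from(d)
        res = AssociationResult(geno.sites.df[["chrom", "pos"]].assign(
            beta=0, se=1, t=0, p=1e-7, neglog10p=7.0), 200, 11, 1, 1, 1)
        ci = candidate_interval(res, 5, geno)
        assert ci.start == ci.end == ci.peak_pos

    def test_ld_block_covered(self):
        rng = np.random.default_rng(15)
        block = _binary(rng, 120, 1)
        cols = []
        for k in range(9):
            noisy = np.abs(block[:, 0] - (rng.random(120) < 0.03))
            cols.append(noisy)
        for k in range(6):
            cols.append(_binary(rng, 120, 1)[:, 0])
        d = np.array(cols).T
        geno = _geno_from(d)
        res = AssociationResult(geno.sites.df[["chrom", "pos"]].assign(
            beta=0, se=1, t=0, p=1e-7, neglog10p=7.0), 120, 15, 1, 1, 1)
        ci = candidate_interval(res, 4, geno)
        pos = geno.sites.df["pos"]
        assert ci.start <= pos.iloc[0] and ci.end >= pos.iloc[8]
        assert all(r2 > 0.6 for r2 in ci.members["r2"].drop(ci.members.index[
            ci.members["pos"] == ci.peak_pos]))

    def test_gene_overlap_listing(self):
        rng = np.random.default_rng(16)
        d = _binary(rng, 50, 3)
        geno = _geno_from(d, start=1000, spacing=100)
        models = GeneModelSet([Gene("gX", "1A", "+", 950, 1150, []),
                               Gene("gY", "1A", "+", 90_000, 95_000, [])])
        res = AssociationResult(geno.sites.df[["chrom", "pos"]].assign(
            beta=0, se=1, t=0, p=1e-7, neglog10p=7.0), 50, 3, 1, 1, 1)
        ci = candidate_interval(res, 0, geno, gene_models=models)
        assert "gX" in ci.genes and "gY" not in ci.genes

    def test_monomorphic_peak_is_error(self):
        d = np.zeros((10, 2))
        d[:, 1] = [0, 1] * 5
        geno = _geno_from(d)
        res = AssociationResult(geno.sites.df[["chrom", "pos"]].assign(
            beta=0, se=1, t=0, p=1.0, neglog10p=0.0), 10, 2, 1, 1, 1)
        with pytest.raises(ValueError):
            candidate_interval(res, 0, geno)


class TestFilterExpressed:
    def test_strict_threshold_in_all_tissues(self):
        expr = ExpressionTable(pd.DataFrame(
            {"root": [2.0, 2.0, 1.0, 5.0], "shoot": [0.5, 3.0, 1.0, 2.0]},
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene")))
        got = filter_expressed(["g1", "g2", "g3", "g4", "g5"], expr)
        # g1 fails shoot, g3 fails the strict > 1, g5 is absent (TPM 0)
        assert got == ["g2", "g4"]

    def test_hand_filter_on_toy_table(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(10)]
        root = rng.uniform(0, 4, 10)
        shoot = rng.uniform(0, 4, 10)
        expr = ExpressionTable(pd.DataFrame({"root": root, "shoot": shoot},
                                            index=pd.Index(genes, name="gene")))
        expected = [g for g, r, s in zip(genes, root, shoot) if r > 1 and s > 1]
        assert filter_expressed(genes, expr) == expected
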
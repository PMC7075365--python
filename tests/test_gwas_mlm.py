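import numpy as np
import pytest

from coreset_gbs.gwas_mlm import (
    allele_class_effects,
    bonferroni_threshold,
    genomic_inflation,
    kinship,
    manhattan_table,
    mlm_associate,
    pca_covariates,
    q_covariates,
    qq_table,
)
from coreset_gbs.io_formats import MISSING
from coreset_gbs.popgen_stats import ibs_distance
from coreset_gbs.synthetic_data import (
    PanelSimConfig,
    TraitSimConfig,
    simulate_panel,
    simulate_traits,
)

from conftest import make_geno


class TestKinship:
    def test_duplicates_maximal_similarity(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        d[1] = d[0]
        K = kinship(make_geno(d), method="ibs-similarity")
        assert K.values[0, 1] == pytest.approx(1.0 + 0.0, abs=1e-9)
        # diagonal dominates its row
        for i in range(5):
            assert K.values[i, i] >= K.values[i].max() - 1e-12

    def test_symmetric_psd(self, small_panel):
        geno, _ = small_panel
        for method in ("ibs-similarity", "centered-cross-product"):
            K = kinship(geno, method=method)
            assert np.allclose(K.values, K.values.T)
            w = np.linalg.eigvalsh(K.values)
            assert w.min() > -1e-8

    def test_centered_cross_product_hand_oracle(self):
        d = np.array(
            [[0, 1, 2, 0, 1, 2],
             [1, 1, 0, 2, 0, 1],
             [2, 0, 1, 1, 2, 0],
             [0, 2, 2, 1, 1, 1]], dtype=np.int8
        )
        K = kinship(make_geno(d), method="centered-cross-product")
        p = d.mean(axis=0) / 2
        z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = z @ z.T / d.shape[1] + 1e-6 * np.eye(4)
        np.testing.assert_allclose(K.values, expected, atol=1e-10)

    def test_empty_sites_errors(self):
        geno = make_geno(np.zeros((3, 1), dtype=np.int8)).take_sites([])
        with pytest.raises(ValueError, match="empty"):
            kinship(geno)

    def test_ibs_is_one_minus_distance(self, small_panel):
        geno, _ = small_panel
        K = kinship(geno, method="ibs-similarity")
        D = ibs_distance(geno)
        np.testing.assert_allclose(
            K.values - 1e-6 * np.eye(geno.n_samples), 1.0 - D.values, atol=1e-12
        )


class TestPcaCovariates:
    def test_separates_two_populations(self):
        cfg = PanelSimConfig(n_samples=60, n_sites=400, n_subpops=2, fst=0.3,
                             admixture_alpha=0.05, missing_rate=0.0, seed=5)
        geno, truth = simulate_panel(cfg)
        cov = pca_covariates(geno, n_pcs=2)
        pc1 = cov.values[:, 0]
        labels = truth.subpop_of
        if len(set(labels)) == 2:
            m0 = pc1[labels == 0].mean()
            m1 = pc1[labels == 1].mean()
            spread = pc1.std()
            assert abs(m0 - m1) > spread  # clear separation

    def test_orthogonal_components(self, small_panel):
        geno, _ = small_panel
        cov = pca_covariates(geno, n_pcs=3)
        g = cov.values
        gram = g.T @ g
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_monomorphic_site_zero_loading(self):
        d = np.array(
            [[0, 1, 2], [0, 2, 0], [0, 0, 1], [0, 1, 2], [0, 2, 1]], dtype=np.int8
        )
        cov = pca_covariates(make_geno(d), n_pcs=1)
        # removing the monomorphic column changes nothing
        cov2 = pca_covariates(make_geno(d[:, 1:]), n_pcs=1)
        np.testing.assert_allclose(cov.values, cov2.values, atol=1e-10)

    def test_bad_n_pcs_errors(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(ValueError):
            pca_covariates(geno, n_pcs=0)

    def test_deterministic_sign(self, small_panel):
        geno, _ = small_panel
        a = pca_covariates(geno, 3).values
        b = pca_covariates(geno, 3).values
        np.testing.assert_array_equal(a, b)


class TestQCovariates:
    def test_drops_one_column(self):
        q = np.array([[0.2, 0.3, 0.5], [0.6, 0.3, 0.1], [0.1, 0.8, 0.1]])
        cov = q_covariates(["a", "b", "c"], q)
        assert cov.values.shape == (3, 2)
        assert cov.kind == "Q"


class TestMlmAssociate:
    def test_ols_limit_matches_statsmodels(self):
        """With K = identity and no covariates, p equals the OLS F-test p."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n, m = 30, 12
        d = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        geno = make_geno(d)
        y = rng.normal(size=n) + 0.5 * d[:, 3]
        records, fit = mlm_associate(y, geno, covariates=None, K=None, mode="p3d")
        for j, rec in enumerate(records):
            x = sm.add_constant(d[:, j].astype(float))
            ols = sm.OLS(y, x).fit()
            assert rec.p_value == pytest.approx(ols.f_pvalue, abs=1e-8)
            assert rec.beta == pytest.approx(ols.params[1], abs=1e-8)
            assert rec.marker_r2 == pytest.approx(ols.rsquared, abs=1e-8)

    def test_constant_phenotype_errors(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(ValueError, match="constant"):
            mlm_associate(np.ones(geno.n_samples), geno)

    def test_kinship_label_mismatch_errors(self, small_panel):
        geno, _ = small_panel
        K = kinship(geno.take_samples(geno.sample_ids[:10]))
        y = np.random.default_rng(0).normal(size=geno.n_samples)
        with pytest.raises(ValueError, match="labels"):
            mlm_associate(y, geno, K=K)

    def test_missing_phenotypes_dropped(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=(25, 6)).astype(np.int8)
        geno = make_geno(d)
        y = rng.normal(size=25)
        y[:5] = np.nan
        records, fit = mlm_associate(y, geno)
        assert fit.n == 20
        assert all(r.n_used == 20 for r in records)

    def test_missing_dosages_pairwise_deletion(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, size=(30, 4)).astype(np.int8)
        d[0, 2] = MISSING
        geno = make_geno(d)
        y = rng.normal(size=30)
        records, _ = mlm_associate(y, geno)
        assert records[2].n_used == 29
        assert records[0].n_used == 30
        # subsetted marker equals a direct OLS on the complete pairs
        import statsmodels.api as sm

        ok = d[:, 2] != MISSING
        ols = sm.OLS(y[ok], sm.add_constant(d[ok, 2].astype(float))).fit()
        assert records[2].p_value == pytest.approx(ols.f_pvalue, abs=1e-8)

    def test_p3d_and_exact_agree_on_simulated_panel(self):
        """Sanity bound: under a polygenic (no large single-marker) trait the
        two modes give the same -log10 p within 0.2 for every marker."""
        cfg = PanelSimConfig(n_samples=150, n_sites=120, seed=21, missing_rate=0.0)
        geno, truth = simulate_panel(cfg)
        pheno, _ = simulate_traits(
            geno, TraitSimConfig(h2=0.4, polygenic_share=1.0, season_r=0.9, seed=3)
        )
        y = pheno.trait_vector("MLL", "spring", geno.sample_ids)
        K = kinship(geno)
        r1, _ = mlm_associate(y, geno, K=K, mode="p3d")
        r2, _ = mlm_associate(y, geno, K=K, mode="exact")
        diffs = [
            abs(-np.log10(a.p_value) + np.log10(b.p_value))
            for a, b in zip(r1, r2)
            if np.isfinite(a.p_value) and np.isfinite(b.p_value)
        ]
        assert np.quantile(diffs, 0.95) < 0.2
        assert np.mean(diffs) < 0.05


class TestAlleleClassEffects:
    def test_major_effect_definition(self):
        y = np.array([10.0, 10.0, 8.0, 8.0, 9.0])
        d = np.array([0, 0, 2, 2, 1])
        major, minor, maf, maj_eff, min_eff, counts = allele_class_effects(y, d)
        grand = y.mean()
        assert maj_eff == pytest.approx(10.0 - grand)
        assert min_eff == pytest.approx(8.0 - grand)
        assert counts == (2, 1, 2)

    def test_counts_sum(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=40)
        y = rng.normal(size=40)
        *_, counts = allele_class_effects(y, d)
        assert sum(counts) == 40

    def test_empty_minor_class(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([0, 0, 0, 1])
        *_, maj_eff, min_eff, counts = allele_class_effects(y, d)
        assert np.isnan(min_eff)
        assert counts == (3, 1, 0)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            allele_class_effects(np.array([1.0]), np.array([MISSING]))


class TestBonferroni:
    def test_rounding_at_three_significant_digits(self):
        exact, rounded = bonferroni_threshold(0.05, 30282)
        assert rounded == pytest.approx(1.65e-6)
        assert exact == pytest.approx(0.05 / 30282, rel=1e-12)

    def test_trivial_cases(self):
        assert bonferroni_threshold(0.05, 1)[0] == 0.05
        assert bonferroni_threshold(0.01, 10)[0] == pytest.approx(0.001)

    def test_zero_m_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestGenomicInflation:
    def test_all_half_is_one(self):
        assert genomic_inflation([0.5] * 100) == pytest.approx(1.0)

    def test_uniform_null(self):
        rng = np.random.default_rng(0)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert 0.97 <= lam <= 1.03

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            genomic_inflation([])

    def test_qq_and_manhattan_tables(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        qq = qq_table(p)
        assert len(qq) == 50
        assert (qq["observed_neglog10p"].diff().dropna() <= 1e-12).all()

        d = rng.binomial(2, 0.5, size=(20, 5)).astype(np.int8)
        geno = make_geno(d)
        y = rng.normal(size=20)
        recs, _ = mlm_associate(y, geno)
        mt = manhattan_table(recs)
        assert set(mt.columns) >= {"chrom", "pos", "p_value", "neglog10p"}
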
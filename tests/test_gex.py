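"""Expression QC, normalization, variable genes, scaling, clustering, scores."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from neotcr import gex


def _adata(X, genes=None, barcodes=None):
    X = np.asarray(X)
    n_cells, n_genes = X.shape
    genes = genes or [f"GENE{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"bc{i}" for i in range(n_cells)]
    return ad.AnnData(
        X=sp.csr_matrix(X.astype(np.int64)),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )


class TestQCMetrics:
    def test_hand_arithmetic(self):
        adata = _adata([[30, 70]], genes=["MT-CO1", "ACTB"])
        m = gex.compute_qc_metrics(adata)
        assert m["n_umi"].iloc[0] == 100
        assert m["n_genes"].iloc[0] == 2
        assert m["pct_mito"].iloc[0] == pytest.approx(0.30)

    def test_no_mito_genes(self):
        adata = _adata([[5, 5], [1, 0]], genes=["A", "B"])
        m = gex.compute_qc_metrics(adata)
        assert (m["pct_mito"] == 0).all()

    def test_zero_umi_cell_flagged(self):
        adata = _adata([[0, 0], [1, 2]], genes=["MT-1", "B"])
        gex.compute_qc_metrics(adata)
        assert adata.obs["zero_umi"].tolist() == [True, False]
        assert adata.obs["pct_mito"].iloc[0] == 0.0

    def test_matches_generator_truth(self, small_config, small_adata):
        adata = small_adata.copy()
        gex.compute_qc_metrics(adata)
        err = np.abs(
            adata.obs["pct_mito"].to_numpy()
            - adata.obs["true_mito_fraction"].to_numpy()
        )
        # Poisson sampling noise around the true fraction
        assert np.median(err) < 0.03
        assert (err < 0.15).all()


class TestFilterCellsGenes:
    def test_toy_matrix_hand_enumeration(self):
        # 5 genes x 6 cells; thresholds chosen so 2 cells and 1 gene fail
        X = np.array([
            # g0  g1  g2  g3  g4
            [5, 3, 2, 1, 0],   # 4 genes -> kept
            [4, 2, 1, 1, 0],   # 4 genes -> kept
            [3, 1, 1, 1, 0],   # 4 genes -> kept
            [2, 1, 1, 1, 0],   # 4 genes -> kept
            [1, 0, 0, 0, 0],   # 1 gene  -> removed (min_genes=2)
            [0, 0, 0, 0, 1],   # 1 gene  -> removed; g4 only seen here
        ])
        adata = _adata(X)
        out = gex.filter_cells_genes(
            adata, min_genes=2, max_genes=5, max_mito=1.0, min_cells_per_gene=3)
        assert out.shape == (4, 4)
        assert "GENE4" not in out.var_names

    def test_gene_filter_uses_raw_matrix(self):
        # gene detected in 3 cells overall but only 2 QC-passing cells stays
        X = np.array([
            [1, 5, 5], [1, 5, 5], [1, 0, 0], [0, 5, 5],
        ])
        adata = _adata(X)
        out = gex.filter_cells_genes(
            adata, min_genes=2, max_genes=10, max_mito=1.0,
            min_cells_per_gene=3)
        assert "GENE0" in out.var_names  # 3 raw cells, 2 retained cells

    def test_all_cells_removed_raises(self):
        adata = _adata([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="no cells pass QC"):
            gex.filter_cells_genes(adata, min_genes=2, max_genes=10,
                                   max_mito=1.0, min_cells_per_gene=1)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        adata = _adata(rng.poisson(1.0, size=(30, 20)))
        once = gex.filter_cells_genes(
            adata, min_genes=3, max_genes=19, max_mito=1.0,
            min_cells_per_gene=3)
        gex.compute_qc_metrics(once)
        twice = gex.filter_cells_genes(
            once, min_genes=3, max_genes=19, max_mito=1.0,
            min_cells_per_gene=3)
        assert once.shape == twice.shape


class TestLogNormalize:
    def test_closed_form(self):
        X = np.zeros((1, 2), dtype=int)
        X[0] = [1, 9999]
        adata = _adata(X)
        gex.log_normalize(adata, scale_factor=1e4)
        val = adata.layers[gex.LOGNORM_LAYER][0, 0]
        assert val == pytest.approx(np.log1p(1.0), abs=1e-12)

    def test_zero_count_is_zero(self):
        adata = _adata([[0, 5], [2, 3]])
        gex.log_normalize(adata)
        assert adata.layers[gex.LOGNORM_LAYER][0, 0] == 0.0

    def test_per_cell_scale_invariance(self):
        X = np.array([[1, 2, 7], [3, 0, 2]])
        a1, a2 = _adata(X), _adata(2 * X)
        gex.log_normalize(a1)
        gex.log_normalize(a2)
        np.testing.assert_allclose(
            np.asarray(a1.layers[gex.LOGNORM_LAYER].todense()),
            np.asarray(a2.layers[gex.LOGNORM_LAYER].todense()),
            atol=1e-12,
        )


class TestVariableGenes:
    def test_zero_variance_gene_scores_zero(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, size=(30, 12))
        X[:, 0] = 3  # constant
        adata = _adata(X)
        res = gex.find_variable_genes(adata, n_top=12)
        assert res.table.loc["GENE0", "vst_score"] == 0.0
        assert res.genes[-1] == "GENE0" or "GENE0" not in res.genes[:5]

    def test_identical_genes_identical_scores(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, size=(40, 12))
        X[:, 1] = X[:, 0]
        adata = _adata(X)
        res = gex.find_variable_genes(adata, n_top=12)
        assert res.table.loc["GENE0", "vst_score"] == pytest.approx(
            res.table.loc["GENE1", "vst_score"], abs=1e-12)

    def test_overdispersed_genes_recovered(self):
        # 10 genes with 5x overdispersion should top the ranking
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_cells, n_genes = 200, 200
            lam = np.full(n_genes, 2.0)
            X = rng.poisson(lam, size=(n_cells, n_genes)).astype(float)
            od = rng.gamma(shape=0.25, scale=8.0, size=(n_cells, 10))
            X[:, :10] = rng.poisson(od)  # var = 5x Poisson at same mean
            adata = _adata(X.astype(int))
            res = gex.find_variable_genes(adata, n_top=20)
            top20 = set(res.genes)
            hits += sum(f"GENE{i}" in top20 for i in range(10))
        assert hits >= 9 * 20  # >= 9 of 10 on average across seeds

    def test_fewer_genes_than_requested_warns(self):
        rng = np.random.default_rng(3)
        adata = _adata(rng.poisson(2.0, size=(20, 10)))
        with pytest.warns(UserWarning, match="returning all"):
            res = gex.find_variable_genes(adata, n_top=50)
        assert len(res.genes) == 10

    def test_scores_nonincreasing(self):
        rng = np.random.default_rng(4)
        adata = _adata(rng.poisson(2.0, size=(50, 30)))
        res = gex.find_variable_genes(adata, n_top=30)
        assert np.all(np.diff(res.scores) <= 1e-12)


class TestScaleWithRegression:
    def _prep(self, X, n_umi=None, pct_mito=None):
        adata = _adata(X)
        gex.compute_qc_metrics(adata)
        if n_umi is not None:
            adata.obs["n_umi"] = n_umi
        if pct_mito is not None:
            adata.obs["pct_mito"] = pct_mito
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(
            np.asarray(X, dtype=float))
        return adata

    def test_covariate_independent_gene_reduces_to_zscore(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(3.0, size=(50, 4))
        adata = self._prep(X, n_umi=np.ones(50), pct_mito=np.zeros(50))
        res = gex.scale_with_regression(adata, ["GENE0"], clip=100.0)
        x = np.asarray(X[:, 0], dtype=float)
        expected = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(res.data[:, 0], expected, atol=1e-10)

    def test_gene_linear_in_covariate_gives_zero_residuals(self):
        n = 30
        n_umi = np.linspace(100, 1000, n)
        X = np.zeros((n, 2))
        X[:, 0] = 0.01 * n_umi + 3.0
        X[:, 1] = np.random.default_rng(6).poisson(2.0, n)
        adata = self._prep(X.astype(int), n_umi=n_umi, pct_mito=np.zeros(n))
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(X)
        res = gex.scale_with_regression(adata, ["GENE0"])
        np.testing.assert_allclose(res.data[:, 0], 0.0, atol=1e-8)

    def test_matches_hand_computed_ols_residuals(self):
        # 3 genes x 5 cells against explicit normal equations
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(5, 3))
        n_umi = np.array([100.0, 220.0, 150.0, 90.0, 300.0])
        pct = np.array([0.01, 0.05, 0.02, 0.08, 0.03])
        adata = self._prep(np.zeros((5, 3), dtype=int), n_umi=n_umi, pct_mito=pct)
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(Y)
        res = gex.scale_with_regression(
            adata, ["GENE0", "GENE1", "GENE2"], clip=1e6)
        X = np.column_stack([np.ones(5), n_umi, pct])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        R = Y - X @ beta
        R = R - R.mean(axis=0)
        R = R / R.std(axis=0, ddof=1)
        np.testing.assert_allclose(res.data, R, atol=1e-10)

    def test_constant_gene_no_division_by_zero(self):
        X = np.ones((20, 2), dtype=int)
        adata = self._prep(X)
        res = gex.scale_with_regression(adata, ["GENE0", "GENE1"])
        assert np.all(res.data == 0.0)

    def test_mean_zero_before_clipping(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(4.0, size=(60, 5))
        adata = self._prep(X)
        res = gex.scale_with_regression(adata, [f"GENE{i}" for i in range(5)],
                                        clip=1e9)
        np.testing.assert_allclose(res.data.mean(axis=0), 0.0, atol=1e-8)


class TestEmbedAndCluster:
    def _scaled(self, data):
        return gex.ScaledMatrix(
            data=data, genes=[f"G{i}" for i in range(data.shape[1])],
            covariates=(), clip=10.0)

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(9)
        centers = np.zeros((2, 40))
        centers[1, 0] = 10.0
        data = np.vstack([
            rng.normal(centers[0], 0.1, size=(200, 40)),
            rng.normal(centers[1], 0.1, size=(200, 40)),
        ])
        res = gex.embed_and_cluster(self._scaled(data), n_pcs=10,
                                    resolution=0.5, seed=0)
        assert res.n_clusters == 2
        truth = np.repeat([0, 1], 200)
        agreement = max(
            (res.labels == truth).mean(), (res.labels == 1 - truth).mean())
        assert agreement >= 0.99

    def test_identical_cells_single_cluster(self):
        data = np.zeros((50, 10))
        res = gex.embed_and_cluster(self._scaled(data), n_pcs=2,
                                    resolution=0.8, seed=0)
        assert res.n_clusters == 1

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(120, 20))
        r1 = gex.embed_and_cluster(self._scaled(data), n_pcs=5, seed=42)
        r2 = gex.embed_and_cluster(self._scaled(data), n_pcs=5, seed=42)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_cluster_sizes_nonincreasing(self):
        rng = np.random.default_rng(11)
        data = np.vstack([
            rng.normal(0, 0.1, size=(150, 10)),
            rng.normal(5, 0.1, size=(80, 10)),
            rng.normal(-5, 0.1, size=(40, 10)),
        ])
        res = gex.embed_and_cluster(self._scaled(data), n_pcs=5,
                                    resolution=0.5, seed=0)
        sizes = np.bincount(res.labels)
        assert np.all(np.diff(sizes) <= 0)
        assert res.labels.min() == 0

    def test_n_pcs_validation(self):
        with pytest.raises(ValueError, match="n_pcs"):
            gex.embed_and_cluster(self._scaled(np.zeros((10, 5))), n_pcs=6)


class TestModuleScore:
    def _norm_adata(self, Y, genes=None):
        adata = _adata(np.asarray(Y, dtype=int), genes=genes)
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(
            np.asarray(Y, dtype=float))
        return adata

    def test_constant_matrix_scores_zero(self):
        Y = np.full((20, 48), 2.0)
        adata = self._norm_adata(Y)
        res = gex.module_score(adata, ["GENE0", "GENE1"], n_bins=4, seed=0)
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)

    def test_shifted_subset_recovers_delta(self):
        # signature genes shifted by +delta in half the cells
        delta = 1.5
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            Y = rng.normal(5.0, 0.5, size=(80, 120))
            Y[:40, :10] += delta
            adata = self._norm_adata(np.abs(Y))
            adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(Y)
            res = gex.module_score(
                adata, [f"GENE{i}" for i in range(10)], n_bins=6,
                n_ctrl=100, seed=seed)
            diffs.append(res.scores[:40].mean() - res.scores[40:].mean())
        assert np.mean(diffs) == pytest.approx(delta, rel=0.10)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(2.0, 1.0, size=(30, 60))
        adata = self._norm_adata(np.abs(Y))
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(Y)
        s1 = gex.module_score(adata, ["GENE3", "GENE7"], seed=5)
        s2 = gex.module_score(adata, ["GENE3", "GENE7"], seed=5)
        np.testing.assert_array_equal(s1.scores, s2.scores)

    def test_missing_genes_dropped_with_warning(self):
        Y = np.full((10, 30), 1.0)
        adata = self._norm_adata(Y)
        with pytest.warns(UserWarning, match="absent"):
            res = gex.module_score(adata, ["GENE0", "NOPE"], n_bins=3)
        assert res.gene_set == ["GENE0"]
        with pytest.raises(ValueError):
            gex.module_score(adata, ["NOPE"], n_bins=3)

    def test_null_expectation_near_zero(self):
        # exchangeable signature vs bin-mates: |mean| < 3 SE over 50 seeds,
        # with the signature redrawn each seed (the exchangeability is over
        # which bin member plays the signature role)
        rng = np.random.default_rng(13)
        Y = rng.normal(3.0, 1.0, size=(40, 200))
        adata = self._norm_adata(np.abs(Y))
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(Y)
        means = []
        for s in range(50):
            sig = [f"GENE{i}"
                   for i in rng.choice(200, size=10, replace=False)]
            means.append(gex.module_score(
                adata, sig, n_bins=10, n_ctrl=50, seed=s).scores.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * max(se, 1e-12)


class TestCellCycle:
    def _adata_with_scores(self):
        rng = np.random.default_rng(14)
        Y = np.abs(rng.normal(2.0, 0.5, size=(30, 60)))
        adata = _adata(Y.astype(int))
        adata.layers[gex.LOGNORM_LAYER] = sp.csr_matrix(Y)
        return adata

    @pytest.mark.parametrize(
        "s,g2m,expected",
        [(-0.1, -0.2, "G1"), (0.1, 0.5, "G2M"), (0.5, 0.1, "S"),
         (0.0, 0.0, "G1")],
    )
    def test_phase_rule(self, s, g2m, expected):
        phase = np.where(
            np.maximum([s], [g2m]) <= 0, "G1",
            np.where(np.asarray([s]) >= [g2m], "S", "G2M"))
        assert phase[0] == expected

    def test_calls_written_to_obs(self):
        adata = self._adata_with_scores()
        res = gex.cell_cycle_score(
            adata, ["GENE0", "GENE1"], ["GENE2", "GENE3"], n_bins=4, seed=0)
        assert set(np.unique(res.phase)) <= {"G1", "S", "G2M"}
        assert (adata.obs["phase"].to_numpy() == res.phase).all()

    def test_empty_lists_rejected(self):
        adata = self._adata_with_scores()
        with pytest.raises(ValueError):
            gex.cell_cycle_score(adata, ["NOPE"], ["GENE2"], n_bins=4)


class TestAgainstScanpy:
    """Cross-checks against an independent implementation."""

    def test_log_normalize_matches_scanpy(self):
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(15)
        X = rng.poisson(2.0, size=(40, 25))
        ours = _adata(X)
        gex.log_normalize(ours, scale_factor=1e4)
        theirs = _adata(X)
        sc.pp.normalize_total(theirs, target_sum=1e4)
        sc.pp.log1p(theirs)
        np.testing.assert_allclose(
            np.asarray(ours.layers[gex.LOGNORM_LAYER].todense()),
            np.asarray(theirs.X.todense()),
            atol=1e-6,
        )

    def test_module_score_correlates_with_scanpy(self):
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(16)
        X = rng.poisson(3.0, size=(100, 150))
        X[:50, :8] += rng.poisson(6.0, size=(50, 8))
        ours = _adata(X)
        gex.log_normalize(ours)
        sig = [f"GENE{i}" for i in range(8)]
        res = gex.module_score(ours, sig, n_bins=10, n_ctrl=50, seed=0)
        theirs = _adata(X)
        sc.pp.normalize_total(theirs, target_sum=1e4)
        sc.pp.log1p(theirs)
        sc.tl.score_genes(theirs, sig, ctrl_size=50, n_bins=10,
                          random_state=0)
        r = np.corrcoef(res.scores, theirs.obs["score"].to_numpy())[0, 1]
        assert r > 0.95
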
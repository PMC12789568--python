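"""QC gates, normalization identities, HVG ordering, clustering contract."""

import numpy as np
import pytest

from sttme.config import PipelineConfig
from sttme.datasets import LOGNORM_LAYER
from sttme.preprocess import (KMeansEngine, embed_and_cluster, normalize,
                              qc_filter, select_hvg)

from conftest import make_adata


def _boundary_dataset():
    """600-gene toy with spots sitting on and just under the QC gates."""
    n_genes = 600
    counts = np.zeros((3, n_genes), dtype=int)
    genes = [f"MT-{j}" if j < 30 else f"G{j}" for j in range(n_genes)]
    # spot 0: total 499 -> removed, first failing gate is umi
    counts[0, 30:529] = 1
    # spot 1: exactly 500 genes detected, total 500, mito exactly 0.05
    counts[1, 30:505] = 1  # 475 non-mito singletons
    counts[1, :25] = 1  # 25 mito singletons -> mito = 25/500 = 0.05
    # spot 2: comfortably clean
    counts[2, 30:590] = 2
    return make_adata(counts, genes=genes, normalized=False)


def test_boundary_spots_follow_strict_inequalities():
    adata = _boundary_dataset()
    kept, report = qc_filter(adata)
    assert list(report.removed.index) == ["s0"]
    assert report.removed.loc["s0", "reason"] == "umi"
    assert list(kept.obs_names) == ["s1", "s2"]  # equality passes every gate


def test_qc_identity_when_no_violations():
    adata = _boundary_dataset()[2:].copy()
    kept, report = qc_filter(adata)
    assert report.n_removed == 0
    assert list(kept.obs_names) == list(adata.obs_names)
    assert (kept.X != adata.X).nnz == 0


def test_qc_idempotent(small_sim):
    adata, _ = small_sim
    once, r1 = qc_filter(adata.copy())
    twice, r2 = qc_filter(once.copy())
    assert r2.n_removed == 0
    assert list(once.obs_names) == list(twice.obs_names)


def test_qc_error_when_everything_removed():
    adata = _boundary_dataset()[:1].copy()
    with pytest.raises(ValueError, match="no spots"):
        qc_filter(adata)


class TestNormalize:
    def test_equal_totals_give_log1p_of_counts(self):
        counts = np.array([[1, 2, 3], [3, 2, 1], [2, 2, 2]])
        adata = make_adata(counts, normalized=False)
        normalize(adata)
        np.testing.assert_allclose(adata.layers[LOGNORM_LAYER].toarray(),
                                   np.log1p(counts), rtol=1e-12)

    def test_scale_invariance_of_one_spot(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, (10, 20)) + 1
        a1 = make_adata(counts, normalized=False)
        doubled = counts.copy()
        doubled[4] *= 2
        a2 = make_adata(doubled, normalized=False)
        normalize(a1)
        normalize(a2)
        np.testing.assert_allclose(a1.layers[LOGNORM_LAYER].toarray()[4],
                                   a2.layers[LOGNORM_LAYER].toarray()[4], rtol=1e-12)

    def test_matches_two_line_recomputation(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, (20, 30)) + (rng.random((20, 30)) < 0.5)
        counts[counts.sum(axis=1) == 0, 0] = 1
        adata = make_adata(counts, normalized=False)
        normalize(adata)
        totals = counts.sum(axis=1, keepdims=True)
        expected = np.log1p(counts * np.median(totals) / totals)
        np.testing.assert_allclose(adata.layers[LOGNORM_LAYER].toarray(),
                                   expected, rtol=1e-9)

    def test_zero_pattern_preserved_and_totals_equal_median(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.0, (15, 25))
        counts[counts.sum(axis=1) == 0, 0] = 1
        adata = make_adata(counts, normalized=False)
        normalize(adata)
        layer = adata.layers[LOGNORM_LAYER].toarray()
        assert np.array_equal(layer == 0, counts == 0)
        prelog = np.expm1(layer)
        med = np.median(counts.sum(axis=1))
        np.testing.assert_allclose(prelog.sum(axis=1), med, rtol=1e-9)

    def test_zero_total_spot_rejected(self):
        counts = np.array([[0, 0], [1, 2]])
        adata = make_adata(counts, normalized=False)
        with pytest.raises(ValueError, match="zero total"):
            normalize(adata)


class TestHVG:
    def test_full_selection_returns_all_genes(self):
        adata = make_adata(np.random.default_rng(0).poisson(2, (10, 8)) + 1)
        assert set(select_hvg(adata, 8)) == set(adata.var_names)
        with pytest.raises(ValueError):
            select_hvg(adata, 9)

    def test_constant_gene_never_precedes_variable_gene(self):
        counts = np.column_stack([np.full(10, 5), np.arange(1, 11)])
        adata = make_adata(counts, genes=["const", "varying"], normalized=False)
        adata.layers[LOGNORM_LAYER] = counts.astype(float)
        assert select_hvg(adata, 1) == ["varying"]

    def test_matches_oracle_sort_on_handmade_dispersions(self):
        rng = np.random.default_rng(3)
        n_genes = 100
        layer = rng.gamma(2.0, 1.0, (40, n_genes))
        genes = [f"g{j:03d}" for j in range(n_genes)]
        adata = make_adata(np.ones((40, n_genes)), genes=genes, normalized=False)
        adata.layers[LOGNORM_LAYER] = layer
        disp = layer.var(axis=0) / layer.mean(axis=0)
        oracle = [g for _, g in sorted(zip(-disp, genes))][:30]
        assert select_hvg(adata, 30) == oracle


class TestClustering:
    def _blobs(self):
        # the blobs differ in expression profile (disjoint gene programs),
        # which survives total-count normalization
        rng = np.random.default_rng(4)
        a = np.column_stack([rng.poisson(30, (60, 3)), rng.poisson(1, (60, 2))])
        b = np.column_stack([rng.poisson(1, (40, 3)), rng.poisson(30, (40, 2))])
        counts = np.vstack([a, b]) + 1
        adata = make_adata(counts)
        return adata, np.array([0] * 60 + [1] * 40)

    def test_separated_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        adata, truth = self._blobs()
        cfg = PipelineConfig(n_hvg=5, n_pcs=3)
        embed_and_cluster(adata, cfg, engine=KMeansEngine(2), seed=0)
        labels = adata.obs["cluster"].astype(int).to_numpy()
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_fixed_seed_reproducible(self):
        a1, _ = self._blobs()
        a2, _ = self._blobs()
        cfg = PipelineConfig(n_hvg=5, n_pcs=3)
        embed_and_cluster(a1, cfg, seed=7)
        embed_and_cluster(a2, cfg, seed=7)
        assert list(a1.obs["cluster"]) == list(a2.obs["cluster"])

    def test_wrong_length_labels_violate_contract(self):
        adata, _ = self._blobs()
        cfg = PipelineConfig(n_hvg=5, n_pcs=3)
        with pytest.raises(ValueError, match="engine returned"):
            embed_and_cluster(adata, cfg, engine=lambda e, seed: np.zeros(3), seed=0)

    def test_full_rank_pca_preserves_geometry(self):
        adata, _ = self._blobs()
        cfg = PipelineConfig(n_hvg=5, n_pcs=5)
        embed_and_cluster(adata, cfg, engine=KMeansEngine(2), seed=0)
        from sttme.datasets import lognorm_dense

        sub = lognorm_dense(adata)
        emb = adata.obsm["X_pca"]
        # distances are preserved when n_pcs reaches the data rank
        d_orig = np.linalg.norm(sub[0] - sub[-1])
        d_emb = np.linalg.norm(emb[0] - emb[-1])
        assert d_emb == pytest.approx(d_orig, rel=1e-6)
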
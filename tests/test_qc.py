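"""QC filtering, normalization and clustering contracts."""

import numpy as np
import pytest

import screg
from screg.qc import EmptyResultError
from .conftest import make_counts


def _three_cell_counts():
    # depths 500 / 5000 / 80000 across 4 genes
    X = np.array([
        [200, 200, 50, 50],
        [2000, 2000, 500, 500],
        [30000, 30000, 10000, 10000],
    ])
    return make_counts(X)


def test_depth_thresholds_select_single_cell():
    adata = _three_cell_counts()
    thr = screg.QCThresholds(min_depth=1000, max_depth=50000, min_genes=0,
                             max_mito_pct=100)
    out = screg.qc_filter(adata, thr)
    assert list(out.obs_names) == ["cell1"]


def test_noop_thresholds_are_identity():
    adata = _three_cell_counts()
    thr = screg.QCThresholds(min_depth=0, max_depth=10**9, min_genes=0,
                             max_mito_pct=100)
    out = screg.qc_filter(adata, thr)
    assert out.n_obs == adata.n_obs
    assert (out.X == adata.X).all()


def test_qc_filter_idempotent(small_dataset):
    adata, _ = small_dataset
    thr = screg.QCThresholds(min_depth=1000, max_depth=50000, min_genes=50,
                             max_mito_pct=10)
    once = screg.qc_filter(adata, thr)
    twice = screg.qc_filter(once, thr)
    assert list(once.obs_names) == list(twice.obs_names)


def test_empty_result_names_binding_threshold():
    adata = _three_cell_counts()
    thr = screg.QCThresholds(min_depth=10**6, max_depth=10**7, min_genes=0,
                             max_mito_pct=100)
    with pytest.raises(EmptyResultError, match="min_depth"):
        screg.qc_filter(adata, thr)


def test_damaged_cells_removed_by_mito_filter(small_dataset):
    adata, _ = small_dataset
    # threshold at twice the baseline mito fraction (5% -> 10%)
    thr = screg.QCThresholds(min_depth=0, max_depth=10**9, min_genes=0,
                             max_mito_pct=10.0)
    out = screg.qc_filter(adata, thr)
    kept = set(out.obs_names)
    damaged = adata.obs.index[adata.obs["is_damaged"]]
    healthy = adata.obs.index[~adata.obs["is_damaged"]]
    removed_damaged = np.mean([b not in kept for b in damaged])
    removed_healthy = np.mean([b not in kept for b in healthy])
    assert removed_damaged >= 0.90
    assert removed_healthy <= 0.05


def test_log_cpm_single_gene_cell():
    adata = make_counts([[7, 0, 0], [3, 3, 3]])
    out = screg.normalize_log_cpm(adata)
    assert out[0, 0] == pytest.approx(np.log1p(1e6))
    assert out[0, 1] == 0.0 and out[0, 2] == 0.0


def test_log_cpm_depth_invariance():
    a = screg.normalize_log_cpm(make_counts([[1, 3, 6]]))
    b = screg.normalize_log_cpm(make_counts([[2, 6, 12]]))
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_cpm_hand_arithmetic():
    out = screg.normalize_log_cpm(make_counts([[1, 3]]))
    np.testing.assert_allclose(np.expm1(out), [[250_000, 750_000]], rtol=1e-12)


def test_log_cpm_zero_depth_errors():
    with pytest.raises(ValueError, match="zero depth"):
        screg.normalize_log_cpm(make_counts([[0, 0], [1, 1]]))


def test_pearson_residuals_zero_when_counts_match_expectation():
    # identical cells: observed always equals expected
    adata = make_counts([[2, 4, 6], [2, 4, 6]])
    r = screg.pearson_residuals(adata, theta=50)
    np.testing.assert_allclose(r, 0.0, atol=1e-12)


def test_pearson_residuals_poisson_limit():
    X = np.array([[5, 1, 0], [2, 8, 3]])
    adata = make_counts(X)
    r = screg.pearson_residuals(adata, theta=1e9)
    depth = X.sum(1, keepdims=True).astype(float)
    mu = depth * X.sum(0) / X.sum()
    clip = np.sqrt(X.shape[0])
    np.testing.assert_allclose(r, np.clip((X - mu) / np.sqrt(mu), -clip, clip),
                               atol=1e-6)


def test_pearson_residuals_2x2_closed_form():
    theta = 100.0
    r = screg.pearson_residuals(make_counts([[2, 0], [0, 2]]), theta=theta)
    # every mu_gc = 1; residual = (x - 1)/sqrt(1 + 1/theta)
    v = 1.0 / np.sqrt(1 + 1 / theta)
    np.testing.assert_allclose(r, [[v, -v], [-v, v]], rtol=1e-12)


def test_pearson_residuals_zero_gene_column():
    r = screg.pearson_residuals(make_counts([[2, 0], [3, 0]]), theta=10)
    assert (r[:, 1] == 0).all()


def test_clustering_separates_two_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.3, (100, 2))
    b = rng.normal(5, 0.3, (100, 2))
    X = np.vstack([a, b])
    ca = screg.cluster_cells(X, n_pcs=2, knn_k=10, seed=0)
    assert ca.n_clusters == 2
    assert len(set(ca.labels[:100])) == 1 and len(set(ca.labels[100:])) == 1


def test_clustering_deterministic():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 1, (60, 5)), rng.normal(4, 1, (60, 5))])
    l1 = screg.cluster_cells(X, n_pcs=5, knn_k=8, seed=3).labels
    l2 = screg.cluster_cells(X, n_pcs=5, knn_k=8, seed=3).labels
    assert (l1 == l2).all()


def test_clustering_sizing_errors():
    X = np.random.default_rng(0).normal(size=(10, 4))
    with pytest.raises(ValueError):
        screg.cluster_cells(X, n_pcs=2, knn_k=15, seed=0)
    with pytest.raises(ValueError):
        screg.cluster_cells(X, n_pcs=8, knn_k=2, seed=0)
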
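"""Quality control, normalization and clustering.

QC retains cells by sequencing depth, detected-gene count and mitochondrial
percentage.  Normalization is log-CPM for clustering/signatures and analytic
Pearson residuals (negative-binomial, fixed overdispersion) as the
variance-stabilized representation used for metacell neighbor search.
Clustering is PCA -> kNN graph -> greedy modularity community detection; it
replaces a batch-anchored graph clustering because the synthetic conditions
share one batch, so integration has nothing to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad
import igraph
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


class EmptyResultError(ValueError):
    """No cells survive QC; message names the most binding threshold."""


@dataclass
class QCThresholds:
    min_depth: int = 1000
    max_depth: int = 50000
    min_genes: int = 500
    max_mito_pct: float = 20.0

    def __post_init__(self):
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")
        if not 0 <= self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must be in [0, 100]")


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # cluster id per retained cell, contiguous from 0
    n_clusters: int
    embedding: np.ndarray | None = None  # cells x n_pcs


def _depth_genes_mito(adata: ad.AnnData, mito_prefix: str):
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    depth = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() \
        else np.zeros_like(depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(depth > 0, 100.0 * mito / depth, 0.0)
    return depth, n_genes, mito_pct


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds | None = None,
              mito_prefix: str = "mt-") -> ad.AnnData:
    """Drop cells outside the depth / gene-count / mito-percentage bounds.

    The returned AnnData carries a per-condition removal report in
    ``.uns["qc_report"]`` (rows: condition; columns: cells in, removed per
    criterion, cells out).  Raises :class:`EmptyResultError` naming the
    threshold that individually rejects the most cells if nothing survives.
    """
    thresholds = thresholds or QCThresholds()
    depth, n_genes, mito_pct = _depth_genes_mito(adata, mito_prefix)
    fails = {
        "min_depth": depth < thresholds.min_depth,
        "max_depth": depth > thresholds.max_depth,
        "min_genes": n_genes < thresholds.min_genes,
        "max_mito_pct": mito_pct > thresholds.max_mito_pct,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    if not keep.any():
        binding = max(fails, key=lambda k: int(fails[k].sum()))
        raise EmptyResultError(
            f"no cells pass QC; most binding threshold is {binding} "
            f"(rejects {int(fails[binding].sum())}/{adata.n_obs} cells alone)")

    cond = adata.obs["condition"] if "condition" in adata.obs else pd.Series(
        "all", index=adata.obs_names)
    rows = []
    for c in pd.unique(cond):
        m = (cond == c).to_numpy()
        rows.append({
            "condition": c, "cells_in": int(m.sum()),
            **{f"fail_{k}": int((v & m).sum()) for k, v in fails.items()},
            "cells_out": int((keep & m).sum()),
        })
    out = adata[keep].copy()
    out.uns["qc_report"] = pd.DataFrame(rows).set_index("condition")
    out.obs["depth"] = depth[keep]
    out.obs["n_genes_detected"] = n_genes[keep]
    out.obs["mito_pct"] = mito_pct[keep]
    return out


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def normalize_log_cpm(counts) -> np.ndarray:
    """log(1 + CPM): per-cell counts scaled to one million, then log1p.

    Invariant to per-cell depth scaling; cells with zero depth must be removed
    by QC first.
    """
    X = _dense(counts.X if isinstance(counts, ad.AnnData) else counts)
    depth = X.sum(axis=1)
    if (depth <= 0).any():
        bad = int(np.nonzero(depth <= 0)[0][0])
        raise ValueError(f"cell {bad} has zero depth; run QC filtering first")
    return np.log1p(1e6 * X / depth[:, None])


def pearson_residuals(counts, theta: float = 100.0) -> np.ndarray:
    """Analytic negative-binomial Pearson residuals.

    mu_gc = depth_c * gene_total_g / grand_total;
    r = (x - mu) / sqrt(mu + mu^2/theta), clipped to +/- sqrt(n_cells).
    All-zero genes get a zero residual column.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    X = _dense(counts.X if isinstance(counts, ad.AnnData) else counts)
    depth = X.sum(axis=1)
    gene_tot = X.sum(axis=0)
    grand = X.sum()
    mu = np.outer(depth, gene_tot) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X - mu) / np.sqrt(mu + mu * mu / theta)
    r[:, gene_tot == 0] = 0.0
    clip = np.sqrt(X.shape[0])
    return np.clip(r, -clip, clip)


def _merge_connected_clusters(labels: np.ndarray, edges, weights, knn_k: int,
                              tau: float = 0.015) -> np.ndarray:
    """Merge community pairs that are not separated by a sparse graph cut.

    Modularity maximization over-partitions large homogeneous populations (the
    resolution behavior of dense kNN graphs).  Cluster pairs are merged while
    their summed cross-edge SNN weight exceeds ``tau * knn_k * min(sizes)``:
    fragments of one population share many strongly-overlapping neighborhoods
    across the boundary, whereas genuinely distinct populations touch only
    through sparse, low-overlap edges.  Deterministic: strongest pair first,
    ties by lower cluster ids.
    """
    labels = labels.copy()
    while True:
        sizes = np.bincount(labels)
        cross: dict = {}
        for (a, b), w in zip(edges, weights):
            la, lb = labels[a], labels[b]
            if la != lb:
                key = (min(la, lb), max(la, lb))
                cross[key] = cross.get(key, 0.0) + w
        best, best_c = None, tau
        for (la, lb), w in sorted(cross.items()):
            c = w / (knn_k * min(sizes[la], sizes[lb]))
            if c > best_c:
                best, best_c = (la, lb), c
        if best is None:
            return labels
        labels[labels == best[1]] = best[0]


def cluster_cells(normalized: np.ndarray, n_pcs: int = 20, knn_k: int = 15,
                  seed: int = 0) -> ClusterAssignment:
    """PCA on per-gene standardized expression, kNN graph, greedy modularity.

    Deterministic given the seed; cluster ids are contiguous and ordered by
    decreasing cluster size.
    """
    X = np.asarray(normalized, dtype=float)
    n_cells, n_genes = X.shape
    if knn_k < 2:
        raise ValueError("knn_k must be >= 2")
    if n_cells < knn_k + 1:
        raise ValueError(f"need at least knn_k+1={knn_k + 1} cells, got {n_cells}")
    if n_pcs > min(n_cells, n_genes):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(n_cells, n_genes)}")

    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes before PCA")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    emb = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=seed).fit_transform(Z)
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    # shared-nearest-neighbor (Jaccard) weighting of the kNN graph: edges
    # between cells with few shared neighbors are pruned, which keeps large
    # homogeneous populations from being split by modularity optimization
    nbrhood = [set(map(int, idx[i, 1:])) | {i} for i in range(n_cells)]
    edges, weights = [], []
    seen = set()
    for i in range(n_cells):
        for j in idx[i, 1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a == b or (a, b) in seen:
                continue
            seen.add((a, b))
            jac = len(nbrhood[a] & nbrhood[b]) / len(nbrhood[a] | nbrhood[b])
            if jac >= 1.0 / knn_k:
                edges.append((a, b))
                weights.append(jac)
    order = np.argsort([e[0] * n_cells + e[1] for e in edges])
    g = igraph.Graph(n=n_cells, edges=[edges[i] for i in order], directed=False)
    g.es["weight"] = [weights[i] for i in order]
    comm = g.community_fastgreedy(weights="weight").as_clustering()
    raw = _merge_connected_clusters(np.asarray(comm.membership),
                                    [edges[i] for i in order],
                                    [weights[i] for i in order], knn_k)

    order = np.argsort([-np.sum(raw == c) for c in range(raw.max() + 1)],
                       kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    return ClusterAssignment(labels=labels, n_clusters=int(labels.max()) + 1,
                             embedding=emb)
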
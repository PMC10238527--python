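"""Metacell construction for network inference.

Each cell is merged with its five nearest neighbors — distance sqrt(1 - rho),
rho the Spearman correlation between cells in variance-stabilized expression —
by summing raw counts, the candidate set is randomly subset to at most 500
metacells, and rows are CPM-normalized.  Neighbors may be shared between
metacells; the member map records the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import anndata as ad
import scipy.sparse as sp
from scipy.stats import rankdata, spearmanr


@dataclass
class MetacellMatrix:
    matrix: np.ndarray            # metacells x genes (raw sums, or CPM after normalization)
    genes: list
    members: list = field(default_factory=list)  # per metacell: member cell barcodes
    condition: str | None = None
    is_cpm: bool = False

    @property
    def n_metacells(self) -> int:
        return self.matrix.shape[0]


def spearman_distance(x, y) -> float:
    """sqrt(1 - Spearman rho); 0 for identical orderings, sqrt(2) for reversed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 2")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"sample {name} has zero variance; Spearman rho undefined")
    rho = spearmanr(x, y).statistic
    if abs(rho - 1.0) < 1e-12:   # identical orderings: exactly 0
        return 0.0
    if abs(rho + 1.0) < 1e-12:   # reversed orderings: exactly sqrt(2)
        return float(np.sqrt(2.0))
    return float(np.sqrt(max(0.0, 1.0 - rho)))


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return rankdata(X, axis=1)


def pairwise_spearman_distance(X: np.ndarray) -> np.ndarray:
    """Dense pairwise sqrt(1 - rho) over rows (cells) of X."""
    X = np.asarray(X, dtype=float)
    if (np.ptp(X, axis=1) == 0).any():
        bad = int(np.nonzero(np.ptp(X, axis=1) == 0)[0][0])
        raise ValueError(f"sample {bad} has zero variance; Spearman rho undefined")
    R = _rank_rows(X)
    R -= R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R * R).sum(axis=1))
    rho = (R @ R.T) / np.outer(norm, norm)
    np.clip(rho, -1.0, 1.0, out=rho)
    return np.sqrt(np.clip(1.0 - rho, 0.0, 2.0))


def build_metacells(raw_counts: ad.AnnData, normalized: np.ndarray,
                    k: int = 5) -> MetacellMatrix:
    """One candidate metacell per cell: raw counts of the cell plus its k
    nearest neighbors (self excluded from its neighbor list) summed.

    Neighbor search runs on ``normalized`` (typically Pearson residuals) under
    the sqrt(1 - Spearman rho) metric; distance ties break by ascending cell
    index.
    """
    n_cells = raw_counts.n_obs
    if k >= n_cells:
        raise ValueError(f"k={k} requires more than {n_cells} cells")
    if normalized.shape[0] != n_cells:
        raise ValueError("normalized matrix and raw counts disagree on cell count")
    D = pairwise_spearman_distance(np.asarray(normalized, dtype=float))
    np.fill_diagonal(D, np.inf)
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]

    X = raw_counts.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    X = X.tocsr()
    rows = np.repeat(np.arange(n_cells), k + 1)
    cols = np.column_stack([np.arange(n_cells), nbrs]).ravel()
    S = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_cells, n_cells))
    summed = np.asarray((S @ X).todense())

    barcodes = list(raw_counts.obs_names)
    members = [[barcodes[i]] + [barcodes[j] for j in nbrs[i]] for i in range(n_cells)]
    cond = None
    if "condition" in raw_counts.obs:
        vals = raw_counts.obs["condition"].unique()
        cond = str(vals[0]) if len(vals) == 1 else None
    return MetacellMatrix(matrix=summed, genes=list(raw_counts.var_names),
                          members=members, condition=cond, is_cpm=False)


def subset_and_cpm(metacells: MetacellMatrix, cap: int = 500,
                   seed: int = 0) -> MetacellMatrix:
    """Uniform random subset (without replacement) to at most ``cap`` metacells,
    then scale each row to one million counts."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = metacells.n_metacells
    rng = np.random.default_rng([seed, 37])
    take = np.sort(rng.choice(n, size=min(cap, n), replace=False))
    M = metacells.matrix[take].astype(float)
    totals = M.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("metacell with zero total counts cannot be CPM-normalized")
    M = M * (1e6 / totals)[:, None]
    return MetacellMatrix(matrix=M, genes=list(metacells.genes),
                          members=[metacells.members[i] for i in take],
                          condition=metacells.condition, is_cpm=True)
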
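"""Mutual-information regulatory network inference from metacell CPM profiles.

The stage mirrors the classic bootstrap MI-network recipe: per bootstrap,
pairwise regulator-gene mutual information is thresholded against a permutation
null, indirect edges are removed by the data-processing inequality (DPI), and
edges reproducible across bootstraps are consolidated into a final network.
Regulators are restricted to four declared classes (TFs, co-TFs, signaling,
surface); each class is inferred separately and the class networks are unioned.

Estimator choices (documented in the methods note): equal-frequency binning
with a Miller-Madow-corrected plug-in MI, an exponential upper-tail fit to the
permutation null so that thresholds far below 1/n_permutations remain
reachable, and a binomial test on bootstrap support for consolidation.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, binom
from scipy.special import xlogy

from .metacell import MetacellMatrix
from .abundance import bh_adjust


@dataclass
class Regulon:
    """A regulator with signed, confidence-weighted targets.

    mode in [-1, 1] is the sign/strength of regulation (Spearman correlation
    convention); weights are nonnegative and sum to one within the regulon.
    """

    regulator: str
    targets: list
    modes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.modes = np.asarray(self.modes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.regulator in self.targets:
            raise ValueError(f"regulon {self.regulator} contains itself as target")
        if (self.weights < 0).any():
            raise ValueError("regulon weights must be nonnegative")
        s = self.weights.sum()
        if s > 0:
            self.weights = self.weights / s

    def __len__(self):
        return len(self.targets)


def _bin_ids(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin indices from average ranks (ties share a bin)."""
    n = values.shape[-1]
    r = rankdata(values, axis=-1)
    return np.minimum(((r - 0.5) * bins / n).astype(np.int64), bins - 1)


def _mi_from_counts(cnt: np.ndarray, n: int, corrected: bool) -> np.ndarray:
    """MI (nats) from joint-count arrays of shape (..., bins, bins)."""
    c = cnt.astype(float)
    rx = c.sum(axis=-1)
    cy = c.sum(axis=-2)
    mi = (xlogy(c, c).sum(axis=(-1, -2))
          - xlogy(rx, rx).sum(axis=-1)
          - xlogy(cy, cy).sum(axis=-1)) / n + np.log(n)
    if corrected:
        kxy = (cnt > 0).sum(axis=(-1, -2))
        kx = (rx > 0).sum(axis=-1)
        ky = (cy > 0).sum(axis=-1)
        mi = mi + (kx + ky - kxy - 1) / (2.0 * n)
    return np.maximum(mi, 0.0)


def mutual_information(x, y, bins: int | None = None, corrected: bool = True) -> float:
    """Plug-in mutual information (nats) on equal-frequency bins.

    bins defaults to ceil(sqrt(n)); Miller-Madow bias correction applied unless
    ``corrected=False``.  Constant input gives MI = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 8:
        raise ValueError("x and y must be equal-length 1-d vectors, n >= 8")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in mutual_information; returning 0")
        return 0.0
    n = len(x)
    b = bins or int(np.ceil(np.sqrt(n)))
    bx = _bin_ids(x, b)
    by = _bin_ids(y, b)
    cnt = np.bincount(bx * b + by, minlength=b * b).reshape(b, b)
    return float(_mi_from_counts(cnt, n, corrected))


def _mi_profile(bx: np.ndarray, B: np.ndarray, bins: int) -> np.ndarray:
    """MI of one binned vector ``bx`` (n,) against every row of ``B`` (m, n)."""
    m, n = B.shape
    codes = (np.arange(m, dtype=np.int64)[:, None] * (bins * bins)
             + bx[None, :] * bins + B)
    cnt = np.bincount(codes.ravel(), minlength=m * bins * bins)
    return _mi_from_counts(cnt.reshape(m, bins, bins), n, corrected=True)


@dataclass
class MINull:
    """Permutation null for MI with an exponential upper-tail extrapolation.

    The top 5% of permuted-pair MI values are fitted with a rate-``lam``
    exponential above the 95th percentile ``u``, so cutoffs and p-values remain
    defined for significance levels far below 1/n_perm.
    """

    null_sorted: np.ndarray
    u: float
    lam: float

    def pvalue(self, mi) -> np.ndarray:
        mi = np.atleast_1d(np.asarray(mi, dtype=float))
        n = len(self.null_sorted)
        emp = 1.0 - np.searchsorted(self.null_sorted, mi, side="left") / n
        tail = 0.05 * np.exp(-self.lam * (mi - self.u))
        p = np.where(mi > self.u, tail, emp)
        return np.clip(p, 0.0, 1.0)

    def cutoff(self, alpha: float) -> float:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if alpha >= 0.05:
            return float(np.quantile(self.null_sorted, 1.0 - alpha))
        return float(self.u + np.log(0.05 / alpha) / self.lam)


def fit_mi_null(null_mis: np.ndarray) -> MINull:
    null_mis = np.asarray(null_mis, dtype=float)
    if np.ptp(null_mis) == 0:
        raise ValueError("degenerate null: all permuted MI values identical")
    u = float(np.quantile(null_mis, 0.95))
    exc = null_mis[null_mis > u] - u
    if len(exc) == 0 or exc.mean() == 0:
        raise ValueError("degenerate null: empty exponential tail")
    return MINull(null_sorted=np.sort(null_mis), u=u, lam=float(1.0 / exc.mean()))


def null_mi_threshold(matrix: np.ndarray, n_perm: int = 1000,
                      bins: int | None = None, seed: int = 0,
                      rng: np.random.Generator | None = None,
                      take: np.ndarray | None = None) -> MINull:
    """Fit the MI permutation null on a samples x genes matrix.

    Draws ``n_perm`` random gene pairs, permutes one member of each pair over
    the original samples, and fits the exponential tail to the resulting MI
    sample.  When ``take`` (bootstrap resampling indices) is given, the
    permutation is applied before resampling, so the null carries the same
    duplicate-row alignment as the resampled data — omitting this makes every
    gene pair in a bootstrap look dependent and the cutoff collapses.
    """
    X = np.asarray(matrix, dtype=float)
    n, ng = X.shape
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000 for a stable tail fit")
    if ng < 2:
        raise ValueError("need at least two genes")
    rng = rng or np.random.default_rng([seed, 53])
    if take is None:
        take = np.arange(n)
    m = len(take)
    b = bins or int(np.ceil(np.sqrt(m)))
    gx = rng.integers(0, ng, n_perm)
    gy = rng.integers(0, ng, n_perm)
    XV = X[take][:, gx].T                       # n_perm x m
    Y0 = X[:, gy].T                             # n_perm x n, original rows
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    YV = np.take_along_axis(Y0, perm, axis=1)[:, take]
    BX = _bin_ids(XV, b)
    BY = _bin_ids(YV, b)
    codes = (np.arange(n_perm, dtype=np.int64)[:, None] * (b * b)
             + BX * b + BY)
    cnt = np.bincount(codes.ravel(), minlength=n_perm * b * b)
    null = _mi_from_counts(cnt.reshape(n_perm, b, b), m, corrected=True)
    return fit_mi_null(null)


def _edge_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def dpi_prune(edges, tolerance: float = 0.0):
    """Data-processing-inequality pruning.

    ``edges`` is an iterable of (node_a, node_b, mi) over a simple undirected
    graph.  Triangles are processed in lexicographic (a, b, c) order; in each
    still-complete triangle the minimum-MI edge is removed when its MI is below
    (1 - tolerance) times the smaller of the other two, ties broken by
    lexicographic edge order.  Returns the retained edges as a list of tuples
    in the input's key order.
    """
    if not 0 <= tolerance <= 1:
        raise ValueError("tolerance must be in [0, 1]")
    mi = {}
    adj = defaultdict(set)
    for a, b, m in edges:
        if a == b:
            continue
        k = _edge_key(a, b)
        mi[k] = float(m)
        adj[a].add(b)
        adj[b].add(a)

    triangles = []
    for a in sorted(adj):
        for b in sorted(adj[a]):
            if b <= a:
                continue
            for c in sorted(adj[a] & adj[b]):
                if c > b:
                    triangles.append((a, b, c))

    alive = set(mi)
    for a, b, c in triangles:
        tri = [_edge_key(a, b), _edge_key(a, c), _edge_key(b, c)]
        if not all(e in alive for e in tri):
            continue
        tri.sort(key=lambda e: (mi[e], e))
        weakest, others = tri[0], tri[1:]
        if mi[weakest] < (1.0 - tolerance) * min(mi[e] for e in others):
            alive.discard(weakest)
    return [(a, b, mi[_edge_key(a, b)]) for a, b, _ in
            [(k[0], k[1], None) for k in sorted(alive)]]


def bootstrap_consolidate(metacells: MetacellMatrix, regulator_sets: dict,
                          n_boot: int = 200, alpha: float = 1e-8,
                          n_perm: int = 1000, bins: int | None = 6,
                          dpi_tolerance: float = 0.0, seed: int = 0,
                          support_q: float = 0.05) -> pd.DataFrame:
    """Bootstrap MI network with DPI pruning and binomial-support consolidation.

    Per regulator class: resample metacells with replacement ``n_boot`` times;
    in each bootstrap call edges at the permutation-null cutoff for ``alpha``
    and prune with DPI; finally retain edges whose bootstrap support count is
    significant (BH q < ``support_q``) under Binomial(n_boot, p_bar), p_bar
    being the mean per-bootstrap edge frequency of that class.  Class networks
    are unioned.  Returns a DataFrame (regulator, target, mi, support, p, q)
    with ``mi`` the MI on the full (non-resampled) metacell matrix.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(metacells.matrix, dtype=float)
    n, ng = X.shape
    genes = list(metacells.genes)
    gindex = {g: i for i, g in enumerate(genes)}
    b = bins or int(np.ceil(np.sqrt(n)))

    frames = []
    for ci, (cls, members) in enumerate(sorted(regulator_sets.items())):
        regs = [g for g in members if g in gindex]
        missing = set(members) - set(regs)
        if missing:
            warnings.warn(f"regulator class {cls}: {len(missing)} regulators "
                          f"absent from the matrix, skipped")
        if not regs:
            continue
        reg_idx = np.array([gindex[r] for r in regs])
        rng = np.random.default_rng([seed, 61, ci])
        support: dict = defaultdict(int)
        total_calls = 0
        for _ in range(n_boot):
            take = rng.integers(0, n, n)
            Xb = X[take]
            B = _bin_ids(Xb.T, b)
            null = null_mi_threshold(X, n_perm=n_perm, bins=b, rng=rng, take=take)
            cut = null.cutoff(alpha)
            called = []
            for r, gi in zip(regs, reg_idx):
                mi = _mi_profile(B[gi], B, b)
                mi[gi] = -np.inf  # no self edge
                for ti in np.nonzero(mi >= cut)[0]:
                    called.append((r, genes[ti], float(mi[ti])))
            kept = dpi_prune(called, tolerance=dpi_tolerance)
            total_calls += len(kept)
            for a_, b_, _ in kept:
                support[_edge_key(a_, b_)] += 1

        n_regs = len(regs)
        n_pairs = n_regs * (ng - n_regs) + n_regs * (n_regs - 1) // 2
        if not support:
            continue
        p_bar = total_calls / (n_boot * n_pairs)
        keys = sorted(support)
        sup = np.array([support[k] for k in keys])
        pvals = binom.sf(sup - 1, n_boot, p_bar)
        qvals = bh_adjust(pvals)
        keep = qvals < support_q

        # full-data MI for retained edges
        Bfull = _bin_ids(X.T, b)
        mi_full = {r: _mi_profile(Bfull[gindex[r]], Bfull, b) for r in regs}
        rows = []
        reg_set = set(regs)
        for (a_, b_), s, p_, q_, ok in zip(keys, sup, pvals, qvals, keep):
            if not ok:
                continue
            r, t = (a_, b_) if a_ in reg_set else (b_, a_)
            rows.append((r, t, float(mi_full[r][gindex[t]]), int(s),
                         float(p_), float(q_), cls))
        frames.append(pd.DataFrame(
            rows, columns=["regulator", "target", "mi", "support", "p", "q", "class"]))

    if not frames:
        return pd.DataFrame(
            columns=["regulator", "target", "mi", "support", "p", "q", "class"])
    edges = pd.concat(frames, ignore_index=True)
    # a regulator-regulator pair may surface in two classes; keep best support
    edges = (edges.sort_values(["support", "mi"], ascending=False)
             .drop_duplicates(subset=["regulator", "target"], keep="first")
             .sort_values(["regulator", "target"])
             .reset_index(drop=True))
    return edges


def assemble_regulons(edges: pd.DataFrame, metacells: MetacellMatrix,
                      min_targets: int = 10) -> list:
    """Signed, weighted regulons from consolidated edges.

    mode = Spearman correlation between regulator and target CPM across
    metacells; weight proportional to MI, normalized to sum one per regulon;
    regulators with fewer than ``min_targets`` targets are dropped.
    """
    if edges.empty:
        warnings.warn("no edges; returning empty regulon list")
        return []
    X = np.asarray(metacells.matrix, dtype=float)
    gindex = {g: i for i, g in enumerate(metacells.genes)}
    need = sorted({*edges["regulator"], *edges["target"]})
    ranks = {}
    for g in need:
        v = rankdata(X[:, gindex[g]])
        v = v - v.mean()
        nrm = np.sqrt((v * v).sum())
        ranks[g] = v / nrm if nrm > 0 else v

    regulons = []
    for r, grp in edges.groupby("regulator", sort=True):
        # undirected reg-reg edges also count toward the partner's regulon
        targets = list(grp["target"])
        mis = list(grp["mi"])
        if len(targets) < min_targets:
            continue
        modes = np.array([float(ranks[r] @ ranks[t]) for t in targets])
        regulons.append(Regulon(regulator=r, targets=targets,
                                modes=np.clip(modes, -1, 1),
                                weights=np.asarray(mis, dtype=float)))
    if not regulons:
        warnings.warn(f"no regulator reached min_targets={min_targets}; empty list")
    return regulons
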
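"""Gene-expression signatures and rank-based regulon / gene-set enrichment.

Signatures are signed Z-scores from the Wilcoxon rank-sum test: the two-sided
p-value is mapped through the inverse normal CDF and signed by the rank-biserial
correlation 2U/(n1*n2) - 1.  Enrichment of a regulon in a signature is the
weighted sum of the targets' normal scores (the two-tail core of the aREA
statistic), standard normal under random gene assignment; the proportional
enrichment score (PES) rescales the NES by the extremal configuration so its
sign gives the enrichment direction and |PES| <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm
from scipy.special import ndtri

EXACT_MAX_N = 16  # exact Wilcoxon enumeration up to this combined sample size


@dataclass
class EnrichmentResult:
    set_id: str
    nes: float
    pes: float
    p: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum signed Z
# ---------------------------------------------------------------------------

def _exact_ranksum(pooled_ranks: np.ndarray, n1: int) -> tuple:
    """Exact two-sided rank-sum p for the first n1 pooled observations by
    enumeration of all C(n, n1) group assignments (ties via average ranks)."""
    n = len(pooled_ranks)
    mu = n1 * (n - n1) / 2.0
    u_obs = pooled_ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mu)
    hits = total = 0
    base = n1 * (n1 + 1) / 2.0
    for subset in combinations(range(n), n1):
        u = pooled_ranks[list(subset)].sum() - base
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def wilcoxon_signed_z(group, rest) -> tuple:
    """Signed Z and rank-biserial correlation for group vs rest.

    z = Phi^-1(1 - p/2) signed by the rank-biserial correlation, p the
    two-sided Wilcoxon rank-sum p-value (exact enumeration when
    n1 + n2 <= 16, else normal approximation with tie and continuity
    corrections).  Fully tied data gives (0, 0) with a warning.
    """
    g = np.asarray(group, dtype=float)
    r = np.asarray(rest, dtype=float)
    if len(g) < 1 or len(r) < 1:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(g), len(r)
    pooled = np.concatenate([g, r])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups; degenerate signature")
        return 0.0, 0.0
    ranks = rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    rb = 2.0 * u / (n1 * n2) - 1.0

    if n1 + n2 <= EXACT_MAX_N:
        _, p = _exact_ranksum(ranks, n1)
    else:
        mu = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts ** 3 - counts).sum()
        n = n1 + n2
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:
            return 0.0, 0.0
        # z = Phi^-1(1 - p/2) * sign(rb) collapses to the continuity-corrected
        # z itself on the normal path; computing it directly avoids the p
        # underflow at |z| > ~38
        zc = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
        return float(zc), float(rb)
    p = min(p, 1.0)
    z = 0.0 if p >= 1.0 else float(ndtri(1.0 - p / 2.0)) * float(np.sign(rb))
    return z, float(rb)


class RankSumEngine:
    """Vectorized per-gene rank-sum Z over a fixed cells x genes matrix.

    Ranks and tie corrections are computed once; each group split then costs a
    masked rank sum.  Matches :func:`wilcoxon_signed_z` on the normal-
    approximation path.
    """

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.n = X.shape[0]
        self.ranks = rankdata(X, axis=0)
        tie = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            _, counts = np.unique(X[:, j], return_counts=True)
            tie[j] = (counts.astype(float) ** 3 - counts).sum()
        self.tie = tie

    def signed_z(self, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        n1 = int(mask.sum())
        n2 = self.n - n1
        if n1 < 1 or n2 < 1:
            raise ValueError("group split leaves an empty group")
        u = self.ranks[mask].sum(axis=0) - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((self.n + 1) - self.tie / (self.n * (self.n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            zc = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
        return np.where(var <= 0, 0.0, zc)


def cluster_signatures(normalized: np.ndarray, labels: np.ndarray,
                       genes) -> pd.DataFrame:
    """Cluster-vs-rest Wilcoxon signed-Z signature per cluster.

    Returns genes x clusters DataFrame; singleton clusters are allowed but
    flagged with a warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters for cluster-vs-rest signatures")
    engine = RankSumEngine(normalized)
    cols = {}
    for c in uniq:
        mask = labels == c
        if mask.sum() == 1:
            warnings.warn(f"cluster {c} is a singleton; signature has n1 = 1")
        cols[c] = engine.signed_z(mask)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def scaled_expression_ges(normalized: np.ndarray, genes, cells) -> pd.DataFrame:
    """Per-cell signatures from per-gene standardized (scaled) expression.

    Zero-variance genes are dropped with a warning; returns genes x cells.
    """
    X = np.asarray(normalized, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("scaling requires at least two cells")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes from scaled GES")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return pd.DataFrame(Z.T, index=pd.Index(np.asarray(genes)[keep], name="gene"),
                        columns=cells)


# ---------------------------------------------------------------------------
# NES / PES
# ---------------------------------------------------------------------------

def ges_normal_scores(ges: pd.Series) -> pd.Series:
    """Rank-transform a signature to normal scores Phi^-1(rank / (G + 1))."""
    v = ges.to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("GES contains non-finite scores")
    q = ndtri(rankdata(v) / (len(v) + 1.0))
    return pd.Series(q, index=ges.index)


def _nes(q: np.ndarray, modes: np.ndarray, weights: np.ndarray) -> float:
    return float((weights * modes * q).sum() / np.sqrt((weights ** 2).sum()))


def regulon_nes(ges: pd.Series, regulon, set_id: str | None = None) -> EnrichmentResult:
    """Weighted two-tail rank enrichment of a regulon in a signature.

    NES = sum_i w_i m_i q_i / sqrt(sum_i w_i^2) over the regulon targets found
    in the signature, standard normal under random gene assignment; PES
    rescales by the extremal configuration (targets occupying the most extreme
    normal scores, best weights first).
    """
    q = ges_normal_scores(ges)
    present = [i for i, t in enumerate(regulon.targets) if t in q.index]
    if not present:
        raise ValueError(f"regulon {regulon.regulator}: no targets present in the GES")
    t = [regulon.targets[i] for i in present]
    m = regulon.modes[present]
    w = regulon.weights[present]
    qv = q.loc[t].to_numpy()
    nes = _nes(qv, m, w)
    p = float(2.0 * norm.sf(abs(nes)))

    # extremal NES: heaviest weights paired with the largest normal scores
    top = np.sort(q.to_numpy())[::-1][:len(w)]
    nes_max = float((np.sort(w)[::-1] * top).sum() / np.sqrt((w ** 2).sum()))
    pes = float(np.clip(nes / nes_max, -1.0, 1.0)) if nes_max > 0 else 0.0
    return EnrichmentResult(set_id=set_id or regulon.regulator,
                            nes=nes, pes=pes, p=p)


def set_enrichment(ges: pd.Series, gene_set, set_id: str = "set") -> EnrichmentResult:
    """Unit-weight, unit-mode enrichment (AW = AM = 1) of a gene set."""
    from .network import Regulon  # local import to avoid cycle at module load
    members = [g for g in gene_set if g in ges.index]
    if not members:
        raise ValueError(f"gene set {set_id}: no members present in the GES")
    reg = Regulon(regulator=f"__set__{set_id}", targets=members,
                  modes=np.ones(len(members)),
                  weights=np.full(len(members), 1.0 / len(members)))
    return regulon_nes(ges, reg, set_id=set_id)
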
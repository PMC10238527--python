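"""Cell-type assignment and differential cell-type abundance.

Clusters are mapped to cell types by marker-set enrichment (max positive NES
with BH q < 0.05 across the marker sets; otherwise the pan-endothelial
fallback).  Condition-wise frequency shifts are tested with a Pearson
chi-square over the 2 x T contingency table, with Haberman adjusted
standardized residuals providing per-type two-sided p-values, BH-corrected
across types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p, q <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AbundanceResult:
    comparison: tuple                 # (cond_a, cond_b)
    table: pd.DataFrame               # per-type observed/expected/residual/p/q
    chi2: float
    dof: int
    p_global: float


def abundance_chisq(table: pd.DataFrame, cond_a: str, cond_b: str,
                    adjusted: bool = True) -> AbundanceResult:
    """Chi-square test of cell-type composition between two conditions.

    ``table`` is a condition x cell-type count matrix.  Per-type standardized
    residuals are Haberman-adjusted, r = (O - E) / sqrt(E (1 - p_row)(1 - p_col)),
    approximately standard normal under independence; per-type two-sided
    p-values are read from the ``cond_b`` row (positive residual = the type is
    overrepresented in ``cond_b``) and BH-corrected across types.  Raw
    (unadjusted) residuals are available with ``adjusted=False``.
    """
    for c in (cond_a, cond_b):
        if c not in table.index:
            raise KeyError(f"condition {c!r} not in table")
    sub = table.loc[[cond_a, cond_b]].astype(float)
    if (sub.sum(axis=0) <= 0).any():
        bad = list(sub.columns[sub.sum(axis=0) <= 0])
        raise ValueError(
            f"cell types with zero total counts: {bad}; pool or drop these types")
    O = sub.to_numpy()
    chi2, p_global, dof, E = chi2_contingency(O, correction=False)
    if (E <= 0).any():
        raise ValueError("zero expected count; pool sparse cell types before testing")
    N = O.sum()
    p_row = O.sum(axis=1) / N
    p_col = O.sum(axis=0) / N
    denom = E * (1 - p_row)[:, None] * (1 - p_col)[None, :] if adjusted else E
    resid = (O - E) / np.sqrt(denom)

    r_b = resid[1]
    pvals = 2.0 * norm.sf(np.abs(r_b))
    out = pd.DataFrame({
        "cell_type": sub.columns,
        "observed_a": O[0].astype(int),
        "observed_b": O[1].astype(int),
        "expected_b": E[1],
        "residual": r_b,
        "p": pvals,
        "q": bh_adjust(pvals),
    }).set_index("cell_type")
    return AbundanceResult(comparison=(cond_a, cond_b), table=out,
                           chi2=float(chi2), dof=int(dof), p_global=float(p_global))


def assign_cell_types(cluster_ges: pd.DataFrame, marker_sets: dict,
                      q_thresh: float = 0.05,
                      fallback: str = "pan-EC") -> tuple:
    """Label each cluster with its best-enriched marker set.

    ``cluster_ges`` is a genes x clusters signature matrix.  For each cluster
    the enrichment (NES/PES) of every marker set is computed; the cluster takes
    the label of the maximal-NES set if that NES is positive and significant
    (BH across sets, q < ``q_thresh``); otherwise the fallback label.  Returns
    (mapping cluster -> type, long-format enrichment table).
    """
    from .enrichment import set_enrichment

    if not marker_sets:
        raise ValueError("marker_sets is empty")
    mapping = {}
    rows = []
    for cl in cluster_ges.columns:
        ges = cluster_ges[cl]
        results = []
        for name, members in sorted(marker_sets.items()):
            try:
                res = set_enrichment(ges, members, set_id=name)
            except ValueError:
                warnings.warn(f"marker set {name} has no genes in the signature")
                continue
            results.append(res)
        if not results:
            warnings.warn("no marker set overlaps any signature gene; "
                          f"cluster {cl} -> {fallback}")
            mapping[cl] = fallback
            continue
        qvals = bh_adjust([r.p for r in results])
        best = int(np.argmax([r.nes for r in results]))
        label = results[best].set_id \
            if (results[best].nes > 0 and qvals[best] < q_thresh) else fallback
        mapping[cl] = label
        for r, q in zip(results, qvals):
            rows.append((cl, r.set_id, r.nes, r.pes, r.p, q, label))
    detail = pd.DataFrame(
        rows, columns=["cluster", "marker_set", "nes", "pes", "p", "q", "assigned"])
    return mapping, detail


def celltype_table(conditions, types) -> pd.DataFrame:
    """Condition x cell-type contingency table from per-cell labels."""
    df = pd.crosstab(pd.Series(conditions, name="condition"),
                     pd.Series(types, name="cell_type"))
    return df
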
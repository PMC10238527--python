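"""Master-regulator activity and rescue classification.

Condition-contrast signatures (KO vs WT, rescue vs WT) are scored against every
regulon to give a protein-activity NES per regulator and contrast.  Regulators
significantly active in the knockout contrast whose activity shift collapses
(or flips) in the rescue contrast are called rescued; regulators significant
only under treatment are treatment-specific.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import RankSumEngine, regulon_nes
from .abundance import bh_adjust

CATEGORIES = ("rescued", "partially_rescued", "not_rescued",
              "treatment_specific", "unchanged")


def contrast_signature(normalized: np.ndarray, mask_a, mask_b, genes) -> pd.Series:
    """Per-gene Wilcoxon signed-Z for condition a vs condition b.

    Positive scores mean higher expression in condition a.  Swapping the two
    masks negates every score.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both contrast groups must be nonempty")
    if (mask_a == mask_b).all():
        warnings.warn("contrasting a group against itself; all-zero signature")
        return pd.Series(0.0, index=pd.Index(genes, name="gene"))
    if (mask_a & mask_b).any():
        raise ValueError("contrast groups overlap")
    sel = mask_a | mask_b
    X = np.asarray(normalized, dtype=float)[sel]
    engine = RankSumEngine(X)
    z = engine.signed_z(mask_a[sel])
    return pd.Series(z, index=pd.Index(genes, name="gene"))


def activity_matrix(regulons, ges_collection: pd.DataFrame) -> pd.DataFrame:
    """Regulator x sample matrix of enrichment NES values.

    ``ges_collection`` is genes x samples (cells, metacells or contrasts).
    Regulons with no targets in the signature index are dropped with a warning.
    """
    if not regulons:
        raise ValueError("empty regulon list")
    index = set(ges_collection.index)
    rows = {}
    for reg in regulons:
        if not index.intersection(reg.targets):
            warnings.warn(f"regulon {reg.regulator}: no targets overlap the "
                          f"signatures; dropped from the activity matrix")
            continue
        rows[reg.regulator] = [
            regulon_nes(ges_collection[c], reg).nes for c in ges_collection.columns]
    if not rows:
        raise ValueError("no regulon overlaps the signatures")
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(ges_collection.columns))


def classify_rescue(nes_ko: float, q_ko: float, nes_rescue: float,
                    q_rescue: float, revert_fraction: float = 0.5,
                    q_thresh: float = 0.05, epsilon: float = 0.05) -> str:
    """Classify one regulator's (KO vs WT, rescue vs WT) activity pattern.

    rescued: significant in KO and the rescue activity flips sign or shrinks to
    at most (1 - revert_fraction) of the KO magnitude; not_rescued: rescue
    magnitude within epsilon of (or above) the KO magnitude; partially_rescued:
    in between; treatment_specific: significant only in the rescue contrast;
    unchanged otherwise.
    """
    for v in (nes_ko, q_ko, nes_rescue, q_rescue):
        if not np.isfinite(v):
            raise ValueError("classify_rescue inputs must be finite")
    if q_ko < q_thresh:
        flipped = np.sign(nes_rescue) != np.sign(nes_ko)
        if flipped or abs(nes_rescue) <= (1.0 - revert_fraction) * abs(nes_ko):
            return "rescued"
        if abs(nes_rescue) >= (1.0 - epsilon) * abs(nes_ko):
            return "not_rescued"
        return "partially_rescued"
    if q_rescue < q_thresh:
        return "treatment_specific"
    return "unchanged"


def mr_calls(activity: pd.DataFrame, ko_col: str = "KO_vs_WT",
             rescue_col: str = "rescue_vs_WT", revert_fraction: float = 0.5,
             q_thresh: float = 0.05, epsilon: float = 0.05) -> pd.DataFrame:
    """Rescue classification table from a contrast activity matrix.

    Per contrast, two-sided p = 2(1 - Phi(|NES|)) and BH across regulators;
    categories from :func:`classify_rescue`.
    """
    for c in (ko_col, rescue_col):
        if c not in activity.columns:
            raise KeyError(f"activity matrix lacks contrast column {c!r}")
    nes_ko = activity[ko_col].to_numpy(dtype=float)
    nes_rs = activity[rescue_col].to_numpy(dtype=float)
    q_ko = bh_adjust(2.0 * norm.sf(np.abs(nes_ko)))
    q_rs = bh_adjust(2.0 * norm.sf(np.abs(nes_rs)))
    cats = [classify_rescue(a, qa, b, qb, revert_fraction, q_thresh, epsilon)
            for a, qa, b, qb in zip(nes_ko, q_ko, nes_rs, q_rs)]
    return pd.DataFrame({
        "regulator": activity.index,
        "nes_ko": nes_ko, "q_ko": q_ko,
        "nes_rescue": nes_rs, "q_rescue": q_rs,
        "category": cats,
    }).set_index("regulator")
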
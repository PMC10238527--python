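"""Minimal TSV-driven plotting helpers (dot plot of regulon/set enrichment,
master-regulator activity bars)."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def enrichment_dotplot(detail, x="cluster", y="marker_set", size="nes",
                       color="pes", ax=None):
    """Dot plot in the NES-size / PES-color convention: dot area tracks |NES|
    (significance), color tracks PES (direction)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + detail[x].nunique() * 0.6,
                                      1 + detail[y].nunique() * 0.4))
    xs = {v: i for i, v in enumerate(sorted(detail[x].unique()))}
    ys = {v: i for i, v in enumerate(sorted(detail[y].unique()))}
    sc = ax.scatter([xs[v] for v in detail[x]], [ys[v] for v in detail[y]],
                    s=10 + 20 * np.abs(detail[size]),
                    c=detail[color], cmap="coolwarm", vmin=-1, vmax=1,
                    edgecolor="grey", linewidth=0.3)
    ax.set_xticks(list(xs.values()), list(xs.keys()), rotation=45, ha="right")
    ax.set_yticks(list(ys.values()), list(ys.keys()))
    ax.figure.colorbar(sc, ax=ax, label=color)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax


def mr_barplot(calls, ax=None):
    """Paired KO / rescue NES bars per regulator, colored by category."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + len(calls) * 0.45, 4))
    order = calls.sort_values("nes_ko").index
    pos = np.arange(len(order))
    palette = {"rescued": "#2c7fb8", "partially_rescued": "#7fcdbb",
               "not_rescued": "#d95f0e", "treatment_specific": "#756bb1",
               "unchanged": "#bdbdbd"}
    colors = [palette.get(c, "#bdbdbd") for c in calls.loc[order, "category"]]
    ax.bar(pos - 0.2, calls.loc[order, "nes_ko"], width=0.4,
           color=colors, label="KO vs WT")
    ax.bar(pos + 0.2, calls.loc[order, "nes_rescue"], width=0.4,
           color=colors, alpha=0.5, label="rescue vs WT")
    ax.axhline(0, color="k", linewidth=0.5)
    ax.set_xticks(pos, list(order), rotation=90)
    ax.set_ylabel("NES")
    ax.legend()
    return ax
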
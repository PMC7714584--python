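"""Barplot and bubble-plot views of enrichment tables."""

from __future__ import annotations

import pandas as pd

__all__ = ["enrichment_barplot", "enrichment_bubble"]


def _top(table: pd.DataFrame, category, top: int) -> pd.DataFrame:
    t = table if category is None else table.loc[table["category"] == category]
    return t.nsmallest(top, "p_adj").iloc[::-1]


def enrichment_barplot(table: pd.DataFrame, category: str = None, top: int = 20, ax=None):
    """Horizontal bars: one term per row, gene count on the x axis, bar
    color encoding the adjusted p-value (redder = smaller)."""
    import matplotlib.pyplot as plt

    t = _top(table, category, top)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.35 * max(len(t), 4) + 1))
    colors = plt.cm.RdYlBu(t["p_adj"].rank(pct=True))
    ax.barh(t["name"], t["k"], color=colors)
    ax.set_xlabel("gene count")
    ax.set_ylabel("")
    return ax


def enrichment_bubble(table: pd.DataFrame, category: str = "pathway", top: int = 20, ax=None):
    """Bubble plot: gene ratio on x, one set per row, bubble size = gene
    count, color = adjusted p-value."""
    import matplotlib.pyplot as plt

    t = _top(table, category, top)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * max(len(t), 4) + 1))
    sc = ax.scatter(
        t["gene_ratio"], t["name"], s=60 * t["k"], c=t["p_adj"], cmap="RdYlBu"
    )
    ax.set_xlabel("gene ratio")
    if len(t):
        ax.figure.colorbar(sc, ax=ax, label="adjusted p")
    return ax
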
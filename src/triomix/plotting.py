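"""Convenience plots (requires the optional matplotlib dependency)."""

from __future__ import annotations

import pandas as pd

from .crossomics import PcaSeparation

_GRADE_COLORS = {"osteophytic": "#d62728", "high": "#ff7f0e", "low": "#1f77b4"}


def plot_pca(separation: PcaSeparation, ax=None, title: str | None = None):
    """Scatter the PC1/PC2 sample scores coloured by tissue grade."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    scores = separation.scores
    for grade, sub in scores.groupby("grade"):
        ax.scatter(sub["PC1"], sub.get("PC2", pd.Series(0, index=sub.index)),
                   label=grade, color=_GRADE_COLORS.get(grade), s=30)
    ax.set_xlabel(f"PC1 ({separation.explained[0] * 100:.1f}%)")
    if len(separation.explained) > 1:
        ax.set_ylabel(f"PC2 ({separation.explained[1] * 100:.1f}%)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    return ax


def plot_contrast_logfc(diff_a, diff_b, ax=None):
    """logFC-vs-logFC scatter for two differential result sets."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    shared = diff_a.table.index.intersection(diff_b.table.index)
    ax.scatter(diff_a.table.loc[shared, "logFC"],
               diff_b.table.loc[shared, "logFC"], s=4, alpha=0.4)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"logFC {diff_a.layer} {diff_a.contrast}")
    ax.set_ylabel(f"logFC {diff_b.layer} {diff_b.contrast}")
    return ax
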
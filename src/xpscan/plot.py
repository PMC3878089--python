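"""Generic diagnostic plots: score-vs-position and a PCA scatter."""

from __future__ import annotations

import numpy as np


def plot_scores(scores, thresholds=None, chrom: str | None = None, ax=None):
    """sXPEHH against physical position for one comparison; optionally the
    per-chromosome threshold of the comparison's control breed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    t = scores.table
    if chrom is not None:
        t = t[t["chrom"] == chrom]
    for c in t["chrom"].unique():
        sub = t[t["chrom"] == c]
        ax.plot(sub["pos_bp"] / 1e6, sub["sxpehh"], ".", ms=3, label=f"BTA{c}")
        if thresholds is not None:
            thr = thresholds.threshold(scores.control, c)
            ax.hlines(thr, sub["pos_bp"].min() / 1e6, sub["pos_bp"].max() / 1e6,
                      colors="red", linestyles="dashed", lw=0.8)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("sXPEHH")
    ax.set_title(f"{scores.case} vs {scores.control}")
    return ax


def plot_pca(result, panel, components=(1, 2), ax=None):
    """PCA scatter coloured by breed, axes labelled with variance shares."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    i, j = components
    for breed in panel.breeds():
        ids = panel.individuals_of(breed)
        sub = result.scores.loc[ids]
        ax.scatter(sub[f"PC{i}"], sub[f"PC{j}"], s=12, label=breed)
    ax.set_xlabel(f"PC{i} ({100 * result.importance[i - 1]:.1f}%)")
    ax.set_ylabel(f"PC{j} ({100 * result.importance[j - 1]:.1f}%)")
    ax.legend(fontsize=7)
    return ax
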
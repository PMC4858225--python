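"""Optional matplotlib views: length violins, MA panels, subset shifts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .usage import LENGTH_FEATURES, SUBSETS, length_feature_frame

__all__ = ["length_violins", "ma_plot", "subset_shift_violins"]


def length_violins(annotations: pd.DataFrame, groups: pd.Series,
                   transcripts=None, log: bool = True):
    """Violin grid of full-length/ORF/5'UTR/3'UTR lengths per group.

    Dots mark the 25th, 50th and 75th percentile, the summary the length
    comparisons report.
    """
    feats = length_feature_frame(annotations)
    if transcripts is not None:
        feats = feats.loc[feats.index.intersection(transcripts)]
    feats = feats.assign(group=groups.reindex(feats.index)).dropna(subset=["group"])
    labels = sorted(feats["group"].unique())
    fig, axes = plt.subplots(1, len(LENGTH_FEATURES),
                             figsize=(3.2 * len(LENGTH_FEATURES), 3.2))
    for ax, feature in zip(np.atleast_1d(axes), LENGTH_FEATURES):
        data = [feats.loc[feats["group"] == g, feature].dropna() for g in labels]
        if log:
            data = [np.log10(d + 1) for d in data]
        ax.violinplot(data, showextrema=False)
        for i, d in enumerate(data, start=1):
            ax.scatter([i] * 3, np.percentile(d, [25, 50, 75]),
                       color="black", s=8, zorder=3)
        ax.set_xticks(range(1, len(labels) + 1), labels, rotation=45)
        ax.set_title(feature)
        ax.set_ylabel("log10(nt + 1)" if log else "nt")
    fig.tight_layout()
    return fig


def ma_plot(ma: pd.DataFrame, trends: dict):
    """One MA panel per ORF class with the running-mean trend line."""
    classes = list(trends)
    fig, axes = plt.subplots(1, len(classes), figsize=(3.5 * len(classes), 3.2),
                             sharey=True)
    for ax, cls in zip(np.atleast_1d(axes), classes):
        sub = ma[ma["orf_class"] == cls]
        ax.scatter(sub["A"], sub["M"], s=2, alpha=0.3, color="gray")
        ax.plot(trends[cls]["A"], trends[cls]["M_mean"], color="tab:blue")
        ax.axhline(0, color="black", lw=0.5)
        ax.set_title(cls)
        ax.set_xlabel("A = log2 mean expression")
    np.atleast_1d(axes)[0].set_ylabel("M = log2 KO/WT")
    fig.tight_layout()
    return fig


def subset_shift_violins(subset_calls: pd.DataFrame):
    """Delta weighted 3'UTR length distributions for gene subsets a-d."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    data = [
        subset_calls.loc[subset_calls["subset"] == s, "delta_weighted_utr"]
        for s in SUBSETS
    ]
    present = [(s, d) for s, d in zip(SUBSETS, data) if len(d)]
    ax.violinplot([d for _, d in present], showextrema=False)
    for i, (_, d) in enumerate(present, start=1):
        ax.scatter([i] * 3, np.percentile(d, [25, 50, 75]),
                   color="black", s=8, zorder=3)
    ax.set_xticks(range(1, len(present) + 1), [s for s, _ in present])
    ax.axhline(0, color="black", lw=0.5)
    ax.set_ylabel("delta weighted 3'UTR (nt)")
    fig.tight_layout()
    return fig
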
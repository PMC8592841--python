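"""Figure helpers: methylation bars with CI whiskers, strength box plots,
size-class heatmaps.  All functions take an output path and use the Agg
backend; figures are a convenience view of data the TSV/JSON writers
already carry."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .strength import RunLengthRecord
from .summarize import MethylationSummary

__all__ = ["plot_methylation_bars", "plot_strength_boxes", "plot_size_heatmap"]


def plot_methylation_bars(
    summaries: Sequence[MethylationSummary], path: Union[str, Path]
) -> None:
    """Grouped per-context percentage bars with Wilson 95% CI whiskers."""
    contexts = ("CG", "CHG", "CHH")
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(summaries), 3.2))
    width = 0.8 / len(contexts)
    x = np.arange(len(summaries))
    for ci, ctx in enumerate(contexts):
        heights, los, his = [], [], []
        for s in summaries:
            cs = s.contexts.get(ctx)
            heights.append(0.0 if cs is None else cs.percent)
            los.append(0.0 if cs is None else cs.percent - cs.ci_low)
            his.append(0.0 if cs is None else cs.ci_high - cs.percent)
        ax.bar(
            x + ci * width, heights, width, yerr=[los, his],
            capsize=2, label=ctx,
        )
    ax.set_xticks(x + width)
    ax.set_xticklabels([s.amplicon for s in summaries], rotation=30, ha="right")
    ax.set_ylabel("methylation (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_strength_boxes(
    groups: Mapping[str, Sequence[RunLengthRecord]], path: Union[str, Path]
) -> None:
    """Longest-run box plots: 25th-75th boxes, 10th/90th whiskers, mean dot."""
    labels = list(groups)
    data = [[r.longest for r in groups[g]] for g in labels]
    fig, ax = plt.subplots(figsize=(1.5 + 0.9 * len(labels), 3.2))
    ax.boxplot(
        data, tick_labels=labels, whis=(10, 90), showmeans=True,
        showfliers=False,
        meanprops={"marker": "o", "markerfacecolor": "black", "markeredgecolor": "black"},
    )
    ax.set_ylabel("longest methylated stretch")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_size_heatmap(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    """Size (rows) x sample (columns) heatmap of RPM values."""
    fig, ax = plt.subplots(figsize=(1.5 + 0.8 * matrix.shape[1], 4))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=30, ha="right")
    ax.set_ylabel("small RNA size (nt)")
    fig.colorbar(im, ax=ax, label="RPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
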
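"""Figure helpers: regional beta heatmaps and threshold-scan profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .associate import heatmap_table, threshold_profile


def plot_beta_heatmap(results: pd.DataFrame, threshold: float, path=None):
    """Region x (measure, hemisphere) heatmap of standardized betas."""
    table = heatmap_table(results, threshold)
    fig, ax = plt.subplots(figsize=(6, 10))
    vmax = np.nanmax(np.abs(table.to_numpy())) or 1.0
    im = ax.imshow(table.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(table.shape[1]))
    ax.set_xticklabels(["_".join(c) for c in table.columns], rotation=90)
    ax.set_yticks(range(table.shape[0]))
    ax.set_yticklabels(table.index, fontsize=7)
    ax.set_title(f"standardized beta, P_T cutoff {threshold:g}")
    fig.colorbar(im, ax=ax, label="beta")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_threshold_profiles(results: pd.DataFrame, outcomes: list[str],
                            path=None):
    """ΔadjR² of each outcome across the p-value cutoffs."""
    prof = threshold_profile(results, outcomes)
    fig, axes = plt.subplots(1, len(outcomes), figsize=(3 * len(outcomes), 3),
                             squeeze=False, sharey=True)
    for ax, outcome in zip(axes[0], outcomes):
        vals = prof.loc[outcome]
        ax.bar(range(len(vals)), vals.to_numpy())
        ax.set_xticks(range(len(vals)))
        ax.set_xticklabels([f"{t:g}" for t in vals.index], rotation=45)
        ax.set_title(outcome, fontsize=8)
    axes[0][0].set_ylabel("ΔadjR²")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
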
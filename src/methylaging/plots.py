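"""Minimal figure helpers (bar of mean ± SE acceleration per tissue)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_tissue_summary"]


def plot_tissue_summary(summary: pd.DataFrame, path) -> None:
    """One panel per age band: mean acceleration ± one SE for each tissue."""
    bands = summary.age_band.unique()
    fig, axes = plt.subplots(1, len(bands), figsize=(3.2 * len(bands), 3.2),
                             sharey=True, squeeze=False)
    for ax, band in zip(axes[0], bands):
        sub = summary[summary.age_band == band]
        ax.bar(sub.tissue, sub["mean"], yerr=sub.se, capsize=3)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(f"age {band}", fontsize=9)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    axes[0][0].set_ylabel("age acceleration (years)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
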
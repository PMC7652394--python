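"""Display helpers for posterior-predictive summaries.

Kernel-smoothed density curves with quartile ticks (the classic
predicted-interphase-duration panel) and IQR bar charts.  Smoothing is
display-only; every statistic reported elsewhere comes from the raw
predictive samples.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .prediction import duration_quartiles_iqr

__all__ = ["plot_predictive_densities", "plot_iqr_bars"]


def plot_predictive_densities(
    samples_by_label: dict[str, np.ndarray],
    path: str | Path | None = None,
    x_max: float | None = None,
):
    """KDE curves of predictive duration samples, one per labelled
    condition, with 25/50/75-percentile ticks under each curve."""
    fig, ax = plt.subplots(figsize=(7, 0.9 * len(samples_by_label) + 1.5))
    if x_max is None:
        x_max = max(float(np.percentile(s, 99.5)) for s in samples_by_label.values())
    grid = np.linspace(0, x_max, 512)
    for i, (label, samples) in enumerate(samples_by_label.items()):
        offset = -i * 1.0
        dens = stats.gaussian_kde(samples)(grid)
        dens = dens / dens.max() * 0.85
        ax.fill_between(grid, offset, offset + dens, alpha=0.6, lw=0.8)
        q = duration_quartiles_iqr(samples)
        for key in ("q25", "q50", "q75"):
            ax.plot([q[key], q[key]], [offset, offset + 0.3], color="k", lw=1.0)
        ax.text(x_max, offset + 0.4, label, ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("interphase duration (h)")
    ax.set_yticks([])
    ax.set_xlim(0, x_max)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_iqr_bars(iqr_by_label: dict[str, float], path: str | Path | None = None):
    """Horizontal bars of predictive-duration IQR per condition."""
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(iqr_by_label) + 1.2))
    labels = list(iqr_by_label)
    ax.barh(range(len(labels)), [iqr_by_label[k] for k in labels], color="#808080")
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("IQR of predicted interphase duration (h)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
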
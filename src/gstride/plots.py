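"""Diagnostic plots: normality panels and correlation heatmaps.

Requires matplotlib (optional dependency, ``pip install gstride[plot]``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["normality_panel", "correlation_heatmap"]


def _mpl():
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        return plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install gstride[plot])") from exc


def normality_panel(df: pd.DataFrame, variable: str, by: str = "FALLS",
                    path: str | Path | None = None):
    """Boxplot, density and Q-Q panel of one variable split by group."""
    plt = _mpl()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    groups = [(str(level), pd.to_numeric(sub[variable], errors="coerce").dropna())
              for level, sub in df.groupby(by)]
    axes[0].boxplot([g for _, g in groups], tick_labels=[n for n, _ in groups])
    axes[0].set_title(f"{variable} by {by}")
    for name, g in groups:
        xs = np.linspace(g.min(), g.max(), 200)
        kde = sps.gaussian_kde(g)
        axes[1].plot(xs, kde(xs), label=name)
    axes[1].legend()
    axes[1].set_title("density")
    all_vals = pd.to_numeric(df[variable], errors="coerce").dropna()
    sps.probplot(all_vals, dist="norm", plot=axes[2])
    axes[2].set_title("normal Q-Q")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def correlation_heatmap(r: pd.DataFrame, path: str | Path | None = None):
    """Heatmap of a correlation matrix with annotated coefficients."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(1.2 * len(r.columns) + 2, 0.6 * len(r.index) + 2))
    im = ax.imshow(r.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), r.index)
    for i in range(len(r.index)):
        for j in range(len(r.columns)):
            ax.text(j, i, f"{r.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
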
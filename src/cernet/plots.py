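"""Volcano plot and heatmap export for DE tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .matrix import ExpressionMatrix


def volcano_plot(de_table, path, lfc_threshold: float = 1.0, p_threshold: float = 0.05) -> None:
    """log2FC vs -log10 p, passing features highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ok = de_table["p"].notna()
    x = de_table.loc[ok, "log2fc"]
    y = -np.log10(de_table.loc[ok, "p"].clip(lower=1e-300))
    passing = de_table.loc[ok, "passes"].astype(bool)
    up = passing & (x > 0)
    down = passing & (x < 0)
    ax.scatter(x[~passing], y[~passing], s=6, c="grey", alpha=0.5, label="ns")
    ax.scatter(x[up], y[up], s=8, c="red", label="up")
    ax.scatter(x[down], y[down], s=8, c="blue", label="down")
    ax.axvline(lfc_threshold, ls="--", lw=0.6, c="k")
    ax.axvline(-lfc_threshold, ls="--", lw=0.6, c="k")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.6, c="k")
    ax.set_xlabel("log2 fold change (A / H)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def de_heatmap(matrix: ExpressionMatrix, de_table, path, pseudocount: float = 0.01) -> None:
    """Row-standardized log2 expression of passing features across samples."""
    passing = de_table.loc[de_table["passes"], "feature"]
    sub = matrix.values.loc[passing]
    fig, ax = plt.subplots(figsize=(4, max(2, 0.08 * len(sub))))
    if len(sub):
        log2 = np.log2(sub.to_numpy(dtype=float) + pseudocount)
        z = (log2 - log2.mean(axis=1, keepdims=True))
        sd = log2.std(axis=1, keepdims=True)
        z = np.divide(z, sd, out=np.zeros_like(z), where=sd > 0)
        im = ax.imshow(z, aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
        fig.colorbar(im, ax=ax, label="row z-score")
    ax.set_xticks(range(matrix.n_samples))
    ax.set_xticklabels(matrix.values.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(f"DE {matrix.rna_class}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
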
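"""Publication-style panels: box+scatter feature comparisons, phase-plane
overlays, UMAP embeddings and LDA projection histograms with shuffle-null
insets."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ephys import phase_plane
from .sweeps import StepFamily

_COLORS = ("#2a9d8f", "#7d7d7d", "#8e44ad")


def feature_panels(
    table: pd.DataFrame,
    grouping: str,
    features: list[str],
    comparisons: pd.DataFrame,
    path: str | Path,
    max_panels: int = 12,
) -> None:
    """Scatter + box panels for the most significant features."""
    order = comparisons.sort_values("pvalue").index
    feats = [f for f in order if f in features][:max_panels]
    if not feats:
        return
    groups = sorted(table[grouping].dropna().unique())
    ncol = 4
    nrow = int(np.ceil(len(feats) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.6 * nrow), squeeze=False)
    for ax, feat in zip(axes.ravel(), feats):
        for gi, g in enumerate(groups):
            y = table.loc[table[grouping] == g, feat].dropna().to_numpy(float)
            x = gi + 0.12 * np.random.default_rng(0).standard_normal(y.size)
            ax.plot(x, y, "o", ms=3, alpha=0.5, color=_COLORS[gi % len(_COLORS)])
            if y.size:
                ax.boxplot(
                    [y], positions=[gi], widths=0.5, showfliers=False,
                    medianprops={"color": "k"},
                )
        p = comparisons.loc[feat, "pvalue"] if feat in comparisons.index else np.nan
        ax.set_title(f"{feat}  (p={p:.2g})", fontsize=8)
        ax.set_xticks(range(len(groups)), groups, fontsize=7)
    for ax in axes.ravel()[len(feats):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def phase_plot(families: dict[str, StepFamily], labels: dict[str, str],
               path: str | Path) -> None:
    """Overlay of per-cell rheobase phase-plane curves, colored by group."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    groups = sorted(set(labels.values()))
    for cid, fam in families.items():
        v, d = phase_plane(fam)
        if v.size == 0:
            continue
        gi = groups.index(labels.get(cid, groups[0]))
        ax.plot(v, d, lw=0.6, alpha=0.4, color=_COLORS[gi % len(_COLORS)])
    ax.set_xlabel("membrane potential (mV)")
    ax.set_ylabel("dV/dt (mV/ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def umap_panel(results, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    emb = results.embedding
    for gi, g in enumerate(sorted(emb[results.groupby].unique())):
        sub = emb[emb[results.groupby] == g]
        ax.plot(sub["umap1"], sub["umap2"], "o", ms=4, alpha=0.7,
                color=_COLORS[gi % len(_COLORS)], label=str(g))
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lda_panel(results, path: str | Path) -> None:
    """LDA projection histograms per group, with the shuffle-null inset."""
    fig, ax = plt.subplots(figsize=(5, 4))
    proj = results.lda_projection
    emb_groups = results.groups
    labels = results.embedding[results.groupby]
    for gi, g in enumerate(emb_groups):
        vals = proj[labels.reindex(proj.index) == g].dropna()
        ax.hist(vals, bins=20, alpha=0.6, color=_COLORS[gi % len(_COLORS)],
                label=str(g))
    ax.set_xlabel("LDA projection")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    inset = ax.inset_axes([0.68, 0.68, 0.3, 0.28])
    inset.hist(results.null_scores, bins=20, color="#bbbbbb")
    inset.axvline(results.loo_accuracy, color="r", lw=1.2)
    inset.set_title("shuffle null", fontsize=7)
    inset.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
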
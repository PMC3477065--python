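"""Summary figures: separation bar plot, 3-D PCA scatter, difference heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_separation_summary(summary: pd.DataFrame, path) -> None:
    """Bar plot of category mean paired differences (separated vs pooled vs
    outside CNVs)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"amp_separated": "#c0392b", "del_separated": "#2980b9",
              "no_separation": "#7f8c8d", "no_cnv": "#bdc3c7"}
    ax.bar(summary["category"], summary["mean_diff"],
           color=[colors.get(c, "gray") for c in summary["category"]])
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("mean paired log2 difference\n(metastasis - primary)")
    ax.set_title("Dosage effects: separated by CNV state vs pooled")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_scores(scores: pd.DataFrame, groups: pd.Series, path) -> None:
    """3-D scatter of patient scores on the top three components."""
    fig = plt.figure(figsize=(5, 4.5))
    ax = fig.add_subplot(projection="3d")
    palette = {"early": "#c0392b", "mid": "#f39c12", "late": "#2980b9"}
    for gname in dict.fromkeys(groups):
        sel = scores.loc[groups[groups == gname].index]
        ax.scatter(sel["PC1"], sel["PC2"], sel["PC3"],
                   label=gname, s=60, color=palette.get(gname))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend(title="metastasis age")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_prognostic_heatmap(directions: pd.DataFrame,
                            differences: pd.DataFrame,
                            gene_of: pd.Series, path) -> None:
    """Patients x genes heatmap of paired differences, split by label."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    lim = None
    for ax, label in zip(axes, ("good", "poor")):
        genes = directions.loc[directions["label"] == label, "gene"]
        probes = gene_of.index[gene_of.isin(genes)]
        block = differences.loc[probes].T
        if lim is None:
            lim = float(np.nanpercentile(np.abs(block.to_numpy()), 98))
        im = ax.imshow(block, aspect="auto", cmap="RdBu_r", vmin=-lim,
                       vmax=lim)
        ax.set_title(f"{label} prognosis ({block.shape[1]} genes)")
        ax.set_xlabel("genes")
        ax.set_yticks(range(len(block.index)), block.index, fontsize=7)
    fig.colorbar(im, ax=axes, shrink=0.8,
                 label="paired log2 difference")
    fig.savefig(path, dpi=150)
    plt.close(fig)
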
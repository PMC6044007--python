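"""Matplotlib figures for the QC report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

from .distribution import COVERAGE_CLASSES

__all__ = [
    "plot_metagene",
    "plot_eses_curves",
    "plot_ctest_profiles",
    "plot_dendrogram",
    "plot_pca",
    "plot_mean_sd",
    "plot_consistency",
    "plot_coverage_histogram",
]


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_metagene(profile, path):
    fig, ax = plt.subplots(figsize=(7, 3.5))
    colors = {25: "tab:green", 50: "tab:red", 75: "tab:blue"}
    for q, curve in sorted(profile.quantile_curves.items()):
        ax.plot(profile.positions, curve, color=colors[q], label=f"{q}%")
    for x in (100, 200):
        ax.axvline(x, color="0.6", ls="--", lw=0.8)
    ax.set_xticks([50, 150, 250])
    ax.set_xticklabels(["5'UTR", "CDS", "3'UTR"])
    ax.set_ylabel("standardized coverage")
    ax.set_title(f"{profile.sample_id} (n={profile.n_genes_used} genes)")
    ax.legend(title="quantile", fontsize=8)
    return _save(fig, path)


def plot_eses_curves(result, sample_id, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(1, result.N + 1) / result.N
    ax.plot(x, result.p_curve, label="IP", color="tab:red")
    ax.plot(x, result.q_curve, label="Input", color="tab:blue")
    ax.axvline(result.k / result.N, color="k", lw=1)
    ax.set_xlabel("fraction of bins (sorted by normalized IP signal)")
    ax.set_ylabel("fraction of cumulated signal")
    ax.set_title(
        f"{sample_id}: scale={result.scale_factor:.3f}, "
        f"enriched={100 * result.enriched_fraction:.1f}%"
    )
    ax.legend()
    return _save(fig, path)


def plot_ctest_profiles(profiles: dict, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    for sid, prof in profiles.items():
        ax.plot(prof.fold_grid, 100 * prof.proportions, marker="o", label=sid)
    ax.set_xlabel("fold-enrichment threshold")
    ax.set_ylabel("% of bins significantly enriched")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_dendrogram(dend, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    scipy_dendrogram(
        dend.linkage_matrix, labels=dend.sample_ids, ax=ax, leaf_rotation=90
    )
    ax.set_ylabel("complete-linkage Euclidean distance")
    fig.tight_layout()
    return _save(fig, path)


def plot_pca(pca, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    if pca.scores.shape[1] >= 2:
        xs, ys = pca.scores[:, 0], pca.scores[:, 1]
    else:
        xs, ys = pca.scores[:, 0], np.zeros(len(pca.sample_ids))
    ax.scatter(xs, ys)
    for sid, x, y in zip(pca.sample_ids, xs, ys):
        ax.annotate(sid, (x, y), fontsize=8)
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)" if len(evr) else "PC1")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)" if len(evr) > 1 else "PC2")
    return _save(fig, path)


def plot_mean_sd(curves: dict, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    for sid, c in curves.items():
        ax.plot(c.grid, c.fitted, label=sid)
    ax.set_xlabel("per-gene mean bin count")
    ax.set_ylabel("per-gene SD of bin counts")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_consistency(curves: dict, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.plot(c.grid, c.fitted, label=label)
    ax.set_xlabel("cross-replicate mean (normalized)")
    ax.set_ylabel("cross-replicate SD")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_coverage_histogram(rows: list, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(COVERAGE_CLASSES))
    width = 0.8 / max(len(rows), 1)
    for i, row in enumerate(rows):
        vals = [100 * row.class_fractions[c] for c in COVERAGE_CLASSES]
        ax.bar(x + i * width, vals, width=width, label=row.sample_id)
    ax.set_xticks(x + 0.4)
    ax.set_xticklabels(COVERAGE_CLASSES, rotation=45, fontsize=8)
    ax.set_ylabel("% of exonic bins")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _save(fig, path)
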
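"""The ten diagnostic plots.

Each plot is written as PDF and PNG and its underlying numbers as a TSV, so
pipelines can test plot content without image comparison.  QC plots
(mapped reads, RLE, PCA, clustering, density, boxplot) describe the
experiment in a given state (raw / normalised / RUV-corrected); contrast
plots (MA, volcano, p-value histogram) describe a merged consensus table,
using the engine-averaged logFC and average expression, colouring points by
p_intersect <= alpha and sizing them by the between-engine logFC standard
deviation.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import gaussian_kde

from .experiment_io import CountExperiment
from .normalization import NormFactors, cpm_matrix, no_normalization

logger = logging.getLogger(__name__)

PLOT_FORMATS = ("pdf", "png")


def _save(fig, outdir: Path, stem: str, data: pd.DataFrame) -> list[Path]:
    paths = []
    for fmt in PLOT_FORMATS:
        p = outdir / f"{stem}.{fmt}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)
    data_path = outdir / f"{stem}.tsv"
    data.to_csv(data_path, sep="\t", index=False)
    paths.append(data_path)
    for p in paths:
        logger.info("wrote plot artefact: %s", p)
    return paths


def _group_colors(groups: pd.Series) -> list:
    levels = sorted(groups.astype(str).unique())
    cmap = plt.get_cmap("tab10")
    lut = {g: cmap(i % 10) for i, g in enumerate(levels)}
    return [lut[g] for g in groups.astype(str)]


def render_diagnostics(
    exp: CountExperiment,
    merged: pd.DataFrame | None = None,
    state: str = "raw",
    outdir: str | Path = ".",
    norm: NormFactors | None = None,
    ruv_residuals: np.ndarray | None = None,
    alpha: float = 0.05,
) -> list[Path]:
    """Render every applicable diagnostic plot; returns the written paths.

    The RUV residual plot is skipped with a warning when no residual matrix
    is supplied; contrast plots are skipped when no merged table is given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if norm is None:
        norm = no_normalization(exp.counts)
    y = exp.counts.to_numpy(dtype=float)
    samples = exp.sample_names
    groups = exp.sample_meta["group"]
    colors = _group_colors(groups)
    logcpm = cpm_matrix(y, norm, log=True)
    tag = f"{state}" if state else "raw"
    written: list[Path] = []

    # 1. mapped reads
    fig, ax = plt.subplots(figsize=(6, 4))
    lib = y.sum(axis=0)
    ax.bar(samples, lib, color=colors)
    ax.set_ylabel("assigned reads")
    ax.set_title(f"Mapped reads ({tag})")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    written += _save(
        fig, outdir, f"mapped_reads_{tag}", pd.DataFrame({"sample": samples, "reads": lib})
    )

    # 2. RLE: per-sample deviation of log expression from the gene median
    med = np.median(logcpm, axis=1, keepdims=True)
    rle = logcpm - med
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(rle, tick_labels=samples, showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("relative log expression")
    ax.set_title(f"RLE ({tag})")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    written += _save(
        fig,
        outdir,
        f"rle_{tag}",
        pd.DataFrame(
            {"sample": samples, "median_rle": np.median(rle, axis=0)}
        ),
    )

    # 3. PCA of samples on log-CPM
    centred = logcpm - logcpm.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    pcs = vt[:2].T * s[:2]
    var_frac = s[:2] ** 2 / (s**2).sum()
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(pcs[:, 0], pcs[:, 1], c=colors, s=40)
    for name, (px, py) in zip(samples, pcs):
        ax.annotate(name, (px, py), fontsize=7)
    ax.set_xlabel(f"PC1 ({var_frac[0]:.0%})")
    ax.set_ylabel(f"PC2 ({var_frac[1]:.0%})")
    ax.set_title(f"PCA ({tag})")
    fig.tight_layout()
    written += _save(
        fig,
        outdir,
        f"pca_{tag}",
        pd.DataFrame({"sample": samples, "PC1": pcs[:, 0], "PC2": pcs[:, 1]}),
    )

    # 4. RUV residuals
    if ruv_residuals is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot(np.asarray(ruv_residuals), tick_labels=samples, showfliers=False)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("deviance residual")
        ax.set_title(f"RUV residuals ({tag})")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        written += _save(
            fig,
            outdir,
            f"ruv_residuals_{tag}",
            pd.DataFrame(
                {
                    "sample": samples,
                    "median_residual": np.median(ruv_residuals, axis=0),
                }
            ),
        )
    else:
        warnings.warn("no RUV residuals supplied; residual plot skipped", stacklevel=2)

    # 5. hierarchical clustering of samples (correlation distance)
    if len(samples) >= 3:
        corr = np.corrcoef(logcpm.T)
        dist = 1.0 - corr[np.triu_indices(len(samples), k=1)]
        linkage = hierarchy.linkage(np.maximum(dist, 0.0), method="average")
        fig, ax = plt.subplots(figsize=(6, 4))
        hierarchy.dendrogram(linkage, labels=samples, ax=ax)
        ax.set_ylabel("1 - correlation")
        ax.set_title(f"Hierarchical clustering ({tag})")
        fig.tight_layout()
        written += _save(
            fig,
            outdir,
            f"hclust_{tag}",
            pd.DataFrame(corr, index=samples, columns=samples).reset_index(
                names="sample"
            ),
        )

    # 6. density of log-CPM per sample
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(logcpm.min(), logcpm.max(), 200)
    dens_rows = {"logcpm": grid}
    for j, name in enumerate(samples):
        col = logcpm[:, j]
        if np.ptp(col) > 0:
            dens = gaussian_kde(col)(grid)
        else:
            dens = np.zeros_like(grid)
        ax.plot(grid, dens, color=colors[j], lw=1, label=name)
        dens_rows[name] = dens
    ax.set_xlabel("log2 CPM")
    ax.set_ylabel("density")
    ax.set_title(f"Density ({tag})")
    ax.legend(fontsize=6)
    fig.tight_layout()
    written += _save(fig, outdir, f"density_{tag}", pd.DataFrame(dens_rows))

    # 7. boxplot of log-CPM
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(logcpm, tick_labels=samples, showfliers=False)
    ax.set_ylabel("log2 CPM")
    ax.set_title(f"Boxplot ({tag})")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    written += _save(
        fig,
        outdir,
        f"boxplot_{tag}",
        pd.DataFrame({"sample": samples, "median_logcpm": np.median(logcpm, axis=0)}),
    )

    # contrast plots need a merged table
    if merged is not None:
        sig = merged["p_intersect"] <= alpha
        size = 8.0 + 40.0 * merged["LogFC_sd"].fillna(0.0)
        point_color = np.where(sig.fillna(False), "crimson", "grey")

        # 8. MA
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        ax.scatter(
            merged["AveExpr"], merged["LogFC"], c=point_color, s=size, alpha=0.5,
            linewidths=0,
        )
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xlabel("average log2 CPM (mean of engines)")
        ax.set_ylabel("log2 FC (mean of engines)")
        ax.set_title(f"MA ({tag})")
        fig.tight_layout()
        written += _save(
            fig,
            outdir,
            f"ma_{tag}",
            merged[["ID", "AveExpr", "LogFC", "LogFC_sd", "p_intersect"]],
        )

        # 9. volcano
        with np.errstate(divide="ignore"):
            neglog = -np.log10(np.maximum(merged["p_intersect"].to_numpy(float), 1e-300))
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        ax.scatter(merged["LogFC"], neglog, c=point_color, s=size, alpha=0.5, linewidths=0)
        ax.set_xlabel("log2 FC (mean of engines)")
        ax.set_ylabel("-log10 p_intersect")
        ax.set_title(f"Volcano ({tag})")
        fig.tight_layout()
        volcano_data = merged[["ID", "LogFC", "LogFC_sd", "p_intersect"]].copy()
        volcano_data["neg_log10_p_intersect"] = neglog
        written += _save(fig, outdir, f"volcano_{tag}", volcano_data)

        # 10. p-value histograms (per-engine adjusted p)
        fig, axes = plt.subplots(1, 3, figsize=(9, 3), sharey=True)
        hist_data = {}
        for ax_j, role in zip(axes, ("edger", "deseq", "voom")):
            vals = merged[f"{role}_adj_p"].dropna()
            ax_j.hist(vals, bins=20, range=(0, 1), color="steelblue")
            ax_j.set_title(role)
            ax_j.set_xlabel("adjusted p")
            hist_data[role] = np.histogram(vals, bins=20, range=(0, 1))[0]
        axes[0].set_ylabel("genes")
        fig.suptitle(f"p-value histograms ({tag})")
        fig.tight_layout()
        written += _save(
            fig,
            outdir,
            f"pvalue_hist_{tag}",
            pd.DataFrame(
                {"bin_left": np.linspace(0, 0.95, 20), **hist_data}
            ),
        )
    return written
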
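"""Static plots: DEG heatmap, volcano plot, and ratio boxplots.

Every plot is built from an intermediate data table that the plotting
function also returns, so all quantitative content is testable without
inspecting pixels.  Rendering goes through matplotlib/seaborn and is
format-agnostic (png/svg/pdf chosen by the output suffix).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .insilico import RatioComparison, significance_stars
from .io import SampleMetadata
from .normalization import NormalizedMatrix

__all__ = [
    "PlotSpec",
    "zscore_log2",
    "plot_heatmap",
    "plot_volcano",
    "plot_ratio_boxplot",
]

_FORMATS = {".png", ".svg", ".pdf"}


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options shared by the plot subcommands."""

    kind: str  # heatmap | volcano | ratio_boxplot
    output: str
    top_n: int = 20
    p_threshold: float = 0.05
    lfc_threshold: float = 0.0
    cluster: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("heatmap", "volcano", "ratio_boxplot"):
            raise ValidationError(f"unknown plot kind {self.kind!r}")
        if Path(self.output).suffix.lower() not in _FORMATS:
            raise ValidationError("output format must be png, svg or pdf")
        if self.kind == "heatmap" and self.top_n < 2:
            raise ValidationError("heatmap needs top_n >= 2")


def _check_path(path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _FORMATS:
        raise ValidationError(f"unsupported image format {path.suffix!r} "
                              "(use .png, .svg or .pdf)")
    return path


def zscore_log2(nm: NormalizedMatrix, genes) -> pd.DataFrame:
    """Row-wise z-scores of log2(normalized count + 1) for the given genes.

    A constant gene (zero SD) gets an all-zero row by convention.
    """
    idx = [nm.gene_index(g) for g in genes]
    logv = np.log2(nm.values[idx] + 1.0)
    mu = logv.mean(axis=1, keepdims=True)
    sd = logv.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (logv - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=list(genes), columns=list(nm.sample_ids))


def plot_heatmap(nm: NormalizedMatrix, meta: SampleMetadata, genes,
                 path, cluster: bool = False) -> pd.DataFrame:
    """Heatmap of row-z-scored log2(normalized count + 1).

    Samples are annotated by group; rows are optionally hierarchically
    clustered.  Returns the plotted z-score matrix.
    """
    import seaborn as sns
    import matplotlib.pyplot as plt

    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("heatmap needs at least 2 genes")
    path = _check_path(path)
    meta = meta.aligned_to(nm.sample_ids)
    z = zscore_log2(nm, genes)
    ref, other = meta.levels
    palette = {ref: "#4C72B0", other: "#C44E52"}
    col_colors = pd.Series(
        [palette[g] for g in meta.group], index=list(nm.sample_ids), name="group"
    )
    grid = sns.clustermap(
        z, row_cluster=cluster, col_cluster=False, col_colors=col_colors,
        cmap="vlag", center=0.0, xticklabels=False,
        figsize=(8, max(3, 0.25 * len(genes) + 1.5)),
    )
    grid.ax_heatmap.set_xlabel("samples")
    grid.savefig(path)
    plt.close(grid.fig)
    return z


def plot_volcano(res: pd.DataFrame, path, p_threshold: float = 0.05,
                 lfc_threshold: float = 0.0) -> pd.DataFrame:
    """Volcano plot: log2FC vs -log10(p) with threshold guide lines.

    NA p-values are omitted; p = 0 is clamped to the smallest positive
    float before the log.  Returns the plotted table (columns log2fc,
    neglog10_p, significant).
    """
    import matplotlib.pyplot as plt

    if res.empty:
        raise ValidationError("empty differential-expression table")
    path = _check_path(path)
    keep = res["pvalue"].notna() & res["log2fc"].notna()
    sub = res.loc[keep, ["gene_id", "log2fc", "pvalue"]].copy()
    tiny = np.nextafter(0, 1)
    p = np.maximum(sub["pvalue"].to_numpy(dtype=float), tiny)
    sub["neglog10_p"] = -np.log10(p)
    sub["significant"] = (sub["pvalue"] <= p_threshold) \
        & (sub["log2fc"].abs() >= lfc_threshold)

    fig, ax = plt.subplots(figsize=(6, 5))
    bg = sub[~sub["significant"]]
    fg = sub[sub["significant"]]
    ax.scatter(bg["log2fc"], bg["neglog10_p"], s=6, c="0.7", linewidths=0)
    ax.scatter(fg["log2fc"], fg["neglog10_p"], s=8, c="#C44E52", linewidths=0)
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.8, c="0.3")
    if lfc_threshold > 0:
        ax.axvline(lfc_threshold, ls="--", lw=0.8, c="0.3")
        ax.axvline(-lfc_threshold, ls="--", lw=0.8, c="0.3")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return sub.reset_index(drop=True)


def plot_ratio_boxplot(rc: RatioComparison, path) -> pd.DataFrame:
    """Grouped boxplots of biomarker/EC ratios with the star annotation.

    Requires an evaluated comparison (wilcoxon_p set); the annotation drawn
    is ``significance_stars(rc.wilcoxon_p)``.  Returns the long-format
    table (sample, group, ratio).
    """
    import seaborn as sns
    import matplotlib.pyplot as plt

    if rc.groups is None or rc.wilcoxon_p is None:
        raise ValidationError("evaluate the ratio comparison before plotting")
    path = _check_path(path)
    table = pd.DataFrame({
        "sample": list(rc.sample_ids),
        "group": list(rc.groups),
        "ratio": rc.ratios,
    })
    counts = table["group"].value_counts()
    if len(counts) < 2 or (counts < 1).any():
        raise ValidationError(
            "a group has no ratios left after zero-count exclusion; "
            "consider zero_policy='pseudocount'"
        )
    fig, ax = plt.subplots(figsize=(4, 5))
    order = sorted(counts.index)
    sns.boxplot(data=table, x="group", y="ratio", order=order, ax=ax,
                palette={order[0]: "#4C72B0", order[1]: "#C44E52"})
    sns.stripplot(data=table, x="group", y="ratio", order=order, ax=ax,
                  color="0.2", size=3)
    top = table["ratio"].max()
    ax.text(0.5, top * 1.05, significance_stars(rc.wilcoxon_p),
            ha="center", va="bottom", fontsize=12)
    ax.set_ylabel(f"{rc.biomarker_id} / {rc.ec_id} count ratio")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table
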
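"""Static plot rendering (SVG + PNG, headless).

Every plot has a machine-readable sidecar written by the pipeline; the
renderers here only draw what the sidecar contains.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .ordination import Dendrogram, PcaResult

__all__ = ["render_plot", "PLOT_KINDS"]

PLOT_KINDS = (
    "pca_biplot",
    "effect",
    "ma",
    "dendro_abundance",
    "stripchart",
    "histogram",
)

CLASS_COLOURS = {
    "nonsignificant": "#9e9e9e",
    "effect_only": "#1f77b4",
    "test_significant": "#ff7f0e",
    "both": "#d62728",
}


def _save(fig, path_base: str | Path) -> list[Path]:
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    out = []
    for ext in ("svg", "png"):
        p = base.with_suffix(f".{ext}")
        fig.savefig(p, metadata={"Date": None} if ext == "svg" else None)
        out.append(p)
    plt.close(fig)
    return out


def render_plot(records, kind: str, path_base: str | Path, **style) -> list[Path]:
    """Render one plot kind to ``<path_base>.svg`` and ``.png``.

    ``records`` is the plot's data: a DataFrame for scatter/strip kinds, a
    :class:`PcaResult` (plus optional colour map) for the biplot, or a
    ``(Dendrogram, AbundanceSummary)`` pair for the combined view.  Raises
    on an empty record set.
    """
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}; choose from {PLOT_KINDS}")
    renderer = {
        "pca_biplot": _render_biplot,
        "effect": _render_effect,
        "ma": _render_ma,
        "dendro_abundance": _render_dendro_abundance,
        "stripchart": _render_stripchart,
        "histogram": _render_histogram,
    }[kind]
    return renderer(records, path_base, **style)


def _check_nonempty(df) -> None:
    if df is None or len(df) == 0:
        raise ValueError("empty record set: nothing to plot")


def _scatter_by_class(ax, records: pd.DataFrame) -> None:
    for cls, colour in CLASS_COLOURS.items():
        sub = records[records["class"] == cls]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], s=12, c=colour, label=cls, alpha=0.8)


def _render_effect(records: pd.DataFrame, path_base, **style):
    _check_nonempty(records)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    lim = float(np.nanmax(np.abs(records[["x", "y"]].to_numpy()))) * 1.05 + 1e-9
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)  # |effect| = 1 diagonals
    ax.plot([0, lim], [0, -lim], "k--", lw=0.8)
    _scatter_by_class(ax, records)
    ax.set_xlabel("median within-group difference (diff.win)")
    ax.set_ylabel("median between-group difference (diff.btw)")
    ax.set_title(style.get("title", "Effect plot"))
    ax.legend(fontsize=7)
    return _save(fig, path_base)


def _render_ma(records: pd.DataFrame, path_base, **style):
    _check_nonempty(records)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.axhline(0, color="k", lw=0.8, ls="--")
    _scatter_by_class(ax, records)
    ax.set_xlabel("median CLR abundance (rab.all)")
    ax.set_ylabel("median between-group difference (diff.btw)")
    ax.set_title(style.get("title", "MA plot"))
    ax.legend(fontsize=7)
    return _save(fig, path_base)


def _render_biplot(records, path_base, colours: dict | None = None, **style):
    if isinstance(records, PcaResult):
        pca = records
    else:
        pca = records.get("pca")
        colours = records.get("colours", colours)
    scores = pca.scores
    _check_nonempty(scores)
    loadings = pca.loadings
    fig, ax = plt.subplots(figsize=(6, 5.5))
    # loadings underneath, scaled into the score range
    smax = float(np.abs(scores.iloc[:, :2].to_numpy()).max()) or 1.0
    lmax = float(np.abs(loadings.iloc[:, :2].to_numpy()).max()) or 1.0
    scale = 0.8 * smax / lmax
    for fid, row in loadings.iterrows():
        ax.annotate(
            str(fid),
            (row.iloc[0] * scale, row.iloc[1] * scale),
            color="#cc8888",
            fontsize=5,
            ha="center",
            va="center",
            alpha=0.7,
        )
    cs = (
        [colours.get(s, "#333333") for s in scores.index]
        if colours
        else "#333333"
    )
    ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], c=cs, s=24, zorder=3)
    if colours:
        seen = {}
        for s in scores.index:
            seen.setdefault(colours.get(s, "#333333"), s)
        handles = [
            plt.Line2D([0], [0], marker="o", ls="", color=c, label=str(lab))
            for c, lab in seen.items()
        ]
        ax.legend(handles=handles, fontsize=7, title=style.get("colour_label"))
    ax.set_xlabel(pca.axis_label(0))
    ax.set_ylabel(pca.axis_label(1))
    ax.set_title(style.get("title", "CLR-PCA biplot"))
    ax.axhline(0, color="k", lw=0.5, alpha=0.4)
    ax.axvline(0, color="k", lw=0.5, alpha=0.4)
    return _save(fig, path_base)


def _render_dendro_abundance(records, path_base, **style):
    dendro, summary = records
    if not isinstance(dendro, Dendrogram):
        raise TypeError("expected (Dendrogram, AbundanceSummary)")
    props = summary.proportions
    _check_nonempty(props)
    order = [s for s in dendro.leaf_order() if s in props.columns]
    props = props[order]
    fig, (ax_d, ax_b) = plt.subplots(
        2, 1, figsize=(max(6, 0.4 * len(order)), 7), height_ratios=[1, 2], sharex=False
    )
    _scipy_dendrogram(
        dendro.to_scipy_linkage(),
        labels=dendro.leaf_ids,
        ax=ax_d,
        color_threshold=0,
        link_color_func=lambda _: "#444444",
    )
    ax_d.set_ylabel(f"{dendro.linkage} linkage height")
    ax_d.tick_params(labelsize=6)
    bottom = np.zeros(len(order))
    cmap = matplotlib.colormaps["tab20"]
    xs = np.arange(len(order))
    for i, (group, row) in enumerate(props.iterrows()):
        ax_b.bar(xs, row.to_numpy(), bottom=bottom, label=str(group), color=cmap(i % 20))
        bottom += row.to_numpy()
    ax_b.set_xticks(xs, order, rotation=90, fontsize=6)
    ax_b.set_ylabel("relative abundance")
    ax_b.legend(fontsize=5, ncol=2, loc="upper right")
    fig.suptitle(style.get("title", "Dendrogram and relative abundance"))
    return _save(fig, path_base)


def _render_stripchart(records: pd.DataFrame, path_base, **style):
    _check_nonempty(records)
    categories = list(dict.fromkeys(records["category"]))
    fig, axes = plt.subplots(
        len(categories), 1, figsize=(7, 2.2 * len(categories)), squeeze=False
    )
    rng = np.random.default_rng(0)  # presentation jitter only
    for ax, cat in zip(axes[:, 0], categories):
        sub = records[records["category"] == cat]
        terms = list(dict.fromkeys(sub["go_id"]))
        pos = {t: i for i, t in enumerate(terms)}
        x = sub["go_id"].map(pos) + rng.uniform(-0.15, 0.15, size=len(sub))
        ax.scatter(x, sub["proportion"], s=8, alpha=0.7)
        ax.set_xticks(range(len(terms)), terms, rotation=90, fontsize=5)
        ax.set_title(str(cat), fontsize=8)
        ax.set_ylabel("proportion")
    fig.tight_layout()
    return _save(fig, path_base)


def _render_histogram(records: pd.DataFrame, path_base, **style):
    _check_nonempty(records)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(records["level"].astype(str), records["count"], color="#1f77b4")
    ax.set_ylabel("count")
    ax.set_title(style.get("title", "Metadata frequencies"))
    ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    return _save(fig, path_base)
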
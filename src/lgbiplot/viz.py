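"""Biplot rendering.

Angles carry the meaning in these plots (cosine ~ correlation), so every
figure uses an equal aspect ratio. Row markers (genotypes or trials) are
drawn in red, column markers (environments or locations) in blue, with
optional vectors from the origin to the column markers, and the model's
Scaling/Centering/SVP codes plus goodness of fit annotated in the corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gge import BiplotModel, aea_stats
from .lg import MegaEnvPartition

_GROUP_COLORS = ["tab:green", "tab:purple", "tab:orange", "tab:brown", "tab:pink",
                 "tab:olive", "tab:cyan"]


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options.

    ``label_rows`` / ``label_cols``: True for text labels, False for plain
    dots, or ``"marker"`` to draw the entities as bare '+' marks (the
    convention for de-emphasizing genotypes).
    """

    show_vectors: bool = True
    show_aea: bool = False
    label_rows: bool | str = True
    label_cols: bool | str = True
    annotate_settings: bool = True
    output_format: str = "svg"
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.output_format not in ("svg", "png"):
            raise ValueError(f"output_format must be 'svg' or 'png', got {self.output_format!r}")


def _axis_labels(model: BiplotModel):
    frac = model.variance_fractions()
    return (f"PC1 ({100 * frac[0]:.1f}%)", f"PC2 ({100 * frac[1]:.1f}%)")


def _annotate(ax, model: BiplotModel) -> None:
    s = model.settings
    ax.text(
        0.02, 0.98,
        f"Scaling = {s.scaling}, Centering = {s.centering}, SVP = {s.svp}\n"
        f"GoF = {100 * model.gof:.1f}%",
        transform=ax.transAxes, va="top", ha="left", fontsize=8,
    )


def _scatter(ax, coords, ids, style, color):
    """style: True = dots + labels, False = dots, 'marker' = '+' marks."""
    if style == "marker":
        ax.scatter(coords[:, 0], coords[:, 1], marker="+", color=color, s=30)
        return
    ax.scatter(coords[:, 0], coords[:, 1], marker="o", color=color, s=12)
    if style is True:
        for (x, y), name in zip(coords, ids):
            ax.annotate(name, (x, y), color=color, fontsize=7,
                        xytext=(2, 2), textcoords="offset points")


def build_biplot_figure(model: BiplotModel, spec: PlotSpec = PlotSpec()):
    """Construct (and return) the matplotlib Figure for a biplot."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.axhline(0, color="0.8", lw=0.8, zorder=0)
    ax.axvline(0, color="0.8", lw=0.8, zorder=0)
    if spec.show_vectors:
        for x, y in model.col_coords:
            ax.plot([0, x], [0, y], color="tab:blue", lw=0.6, alpha=0.6, zorder=1)
    _scatter(ax, model.row_coords, model.row_ids, spec.label_rows, "tab:red")
    _scatter(ax, model.col_coords, model.col_ids, spec.label_cols, "tab:blue")
    if spec.show_aea:
        stats = aea_stats(model)
        reach = 1.1 * float(np.abs(model.row_coords).max() or 1.0)
        dx, dy = stats.aea_direction * reach
        ax.annotate("", xy=(dx, dy), xytext=(-dx, -dy),
                    arrowprops=dict(arrowstyle="->", color="0.3", lw=1.0))
    if spec.annotate_settings:
        _annotate(ax, model)
    xlab, ylab = _axis_labels(model)
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.set_aspect("equal", adjustable="datalim")
    return fig


def build_mega_env_figure(
    model: BiplotModel, partition: MegaEnvPartition, spec: PlotSpec = PlotSpec()
):
    """Mega-environment view: trials as '+', mean placements colored by group."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.axhline(0, color="0.8", lw=0.8, zorder=0)
    ax.axvline(0, color="0.8", lw=0.8, zorder=0)
    ax.scatter(model.row_coords[:, 0], model.row_coords[:, 1],
               marker="+", color="tab:red", s=30, zorder=2)
    if spec.label_rows is True:
        for (x, y), name in zip(model.row_coords, model.row_ids):
            ax.annotate(name, (x, y), color="tab:red", fontsize=6,
                        xytext=(2, 2), textcoords="offset points")
    for label in sorted(set(partition.groups.values())):
        members = partition.members(label)
        pts = partition.placements.loc[members].to_numpy()
        color = _GROUP_COLORS[(label - 1) % len(_GROUP_COLORS)]
        ax.scatter(pts[:, 0], pts[:, 1], marker="o", s=45, color=color,
                   zorder=3, label=f"group {label}")
        for (x, y), name in zip(pts, members):
            ax.annotate(name, (x, y), color=color, fontsize=8, fontweight="bold",
                        xytext=(3, 3), textcoords="offset points")
    if spec.annotate_settings:
        _annotate(ax, model)
    ax.legend(loc="lower right", fontsize=8)
    xlab, ylab = _axis_labels(model)
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.set_aspect("equal", adjustable="datalim")
    return fig


def _save(fig, path: str | Path, spec: PlotSpec) -> Path:
    path = Path(path)
    kwargs = {"dpi": spec.dpi}
    if spec.output_format == "svg":
        kwargs["metadata"] = {"Date": None}  # drop the timestamp
    # fixed hashsalt -> stable SVG element ids -> byte-identical re-renders
    with matplotlib.rc_context({"svg.hashsalt": "lgbiplot"}):
        fig.savefig(path, format=spec.output_format, **kwargs)
    plt.close(fig)
    return path


def render_biplot(model: BiplotModel, spec: PlotSpec, path: str | Path) -> Path:
    """Render a biplot to ``path`` (SVG or PNG per the spec)."""
    return _save(build_biplot_figure(model, spec), path, spec)


def render_mega_env_view(
    model: BiplotModel, partition: MegaEnvPartition, spec: PlotSpec, path: str | Path
) -> Path:
    """Render the mega-environment view to ``path``."""
    return _save(build_mega_env_figure(model, partition, spec), path, spec)
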
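"""Declarative plot specifications for centroid/ray/trend PCA plots.

All geometry (points, centroids, rays, trend arrows) lives in a serializable
:class:`PlotSpec` that tests can inspect without rendering; rendering to
PNG/SVG/PDF is a thin matplotlib pass over the spec. Color assignment is a
pure function of the sorted level list, so plots are reproducible across
runs and platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .matrix import SampleAnnotation
from .pca import GroupCentroids, PCAResult, compute_centroids

logger = logging.getLogger(__name__)

# fixed 20-color categorical cycle (matplotlib tab20 hex values); levels
# beyond the cycle reuse colors but get distinct marker shapes
PALETTE: tuple[str, ...] = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
)
MARKERS: tuple[str, ...] = ("o", "s", "^", "D", "v", "P", "X", "*", "<", ">")


@dataclass
class Point:
    sample_id: str
    x: float
    y: float
    color_key: str
    shape_key: str


@dataclass
class Centroid:
    group: str
    x: float
    y: float
    color_key: str


@dataclass
class Ray:
    group: str
    x0: float
    y0: float
    x1: float
    y1: float
    color_key: str


@dataclass
class Arrow:
    x0: float
    y0: float
    x1: float
    y1: float


@dataclass
class PlotSpec:
    """Everything a centroid/ray/trend plot needs, renderer-independent."""

    points: list[Point]
    centroids: list[Centroid]
    rays: list[Ray]
    arrows: list[Arrow] = field(default_factory=list)
    axis_labels: tuple[str, str] = ("PC1", "PC2")
    legend: dict[str, str] = field(default_factory=dict)
    subtitle: str = ""

    def to_json(self) -> str:
        d = asdict(self)
        d["axis_labels"] = list(self.axis_labels)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlotSpec":
        d = json.loads(text)
        return cls(
            points=[Point(**p) for p in d["points"]],
            centroids=[Centroid(**c) for c in d["centroids"]],
            rays=[Ray(**r) for r in d["rays"]],
            arrows=[Arrow(**a) for a in d["arrows"]],
            axis_labels=tuple(d["axis_labels"]),
            legend=d["legend"],
            subtitle=d["subtitle"],
        )


def assign_styles(levels: list[str]) -> dict[str, tuple[str, str]]:
    """Deterministic (color, marker) per level from the sorted level list."""
    styles = {}
    overflow = False
    for i, lev in enumerate(sorted(levels)):
        color = PALETTE[i % len(PALETTE)]
        marker = MARKERS[(i // len(PALETTE)) % len(MARKERS)]
        if i >= len(PALETTE):
            overflow = True
        styles[lev] = (color, marker)
    if overflow:
        logger.info(
            "%d levels exceed the %d-color palette; colors reused with "
            "distinct shapes", len(levels), len(PALETTE),
        )
    return styles


def _axis_labels(r: PCAResult, components: tuple[int, int]) -> tuple[str, str]:
    return tuple(
        f"PC{c} ({100 * r.explained_fraction[c - 1]:.1f}%)" for c in components
    )  # type: ignore[return-value]


def _check_components(r: PCAResult, components: tuple[int, int]) -> None:
    for c in components:
        if not 1 <= c <= r.n_components:
            raise ValueError(
                f"component {c} out of range 1..{r.n_components}"
            )


def build_plot_spec(
    r: PCAResult,
    c: GroupCentroids,
    a: SampleAnnotation,
    variable: str,
    components: tuple[int, int] = (1, 2),
    subtitle: str = "",
) -> PlotSpec:
    """One point per sample, one centroid per group, one ray per
    (group, member) pair, colored per group."""
    _check_components(r, components)
    cx, cy = components[0] - 1, components[1] - 1
    labels = a.labels_for(variable, r.sample_ids)
    styles = assign_styles(list(c.group_labels))
    points, rays = [], []
    centroid_xy = {g: (float(c.centroids[i, cx]), float(c.centroids[i, cy]))
                   for i, g in enumerate(c.group_labels)}
    for i, sid in enumerate(r.sample_ids):
        g = labels.iloc[i]
        color = styles[g][0]
        x, y = float(r.scores[i, cx]), float(r.scores[i, cy])
        points.append(Point(sid, x, y, color_key=g, shape_key=g))
        gx, gy = centroid_xy[g]
        rays.append(Ray(g, gx, gy, x, y, color_key=g))
    centroids = [
        Centroid(g, *centroid_xy[g], color_key=g) for g in c.group_labels
    ]
    legend = {g: g for g in c.group_labels}
    return PlotSpec(
        points=points,
        centroids=centroids,
        rays=rays,
        axis_labels=_axis_labels(r, components),
        legend=legend,
        subtitle=subtitle,
    )


def add_trend(spec: PlotSpec, c: GroupCentroids, order: list[str]) -> PlotSpec:
    """Append K-1 directed arrows connecting centroids in ``order``.

    ``order`` must be a permutation of the observed group labels (ascending
    batch number, ship date, ...).
    """
    if sorted(order) != sorted(c.group_labels):
        raise ValueError(
            f"order {order} is not a permutation of groups {c.group_labels}"
        )
    xy = {g: spec_centroid_xy(spec, g) for g in order}
    arrows = [
        Arrow(*xy[a_], *xy[b_]) for a_, b_ in zip(order[:-1], order[1:])
    ]
    return PlotSpec(
        points=spec.points,
        centroids=spec.centroids,
        rays=spec.rays,
        arrows=list(spec.arrows) + arrows,
        axis_labels=spec.axis_labels,
        legend=spec.legend,
        subtitle=spec.subtitle,
    )


def spec_centroid_xy(spec: PlotSpec, group: str) -> tuple[float, float]:
    for cen in spec.centroids:
        if cen.group == group:
            return (cen.x, cen.y)
    raise KeyError(f"no centroid for group {group!r}")


def dual_variable_spec(
    r: PCAResult,
    a: SampleAnnotation,
    ray_variable: str,
    point_variable: str,
    components: tuple[int, int] = (1, 2),
    subtitle: str = "",
) -> PlotSpec:
    """Centroids/rays grouped by one variable, point colors and shapes by
    another — the two-variable view that exposes hidden dichotomies."""
    _check_components(r, components)
    c = compute_centroids(r, a, ray_variable)
    spec = build_plot_spec(r, c, a, ray_variable, components, subtitle)
    point_labels = a.labels_for(point_variable, r.sample_ids)
    if point_labels.isna().any():
        raise ValueError(f"some samples lack a {point_variable!r} label")
    point_styles = assign_styles(sorted(point_labels.unique()))
    for i, p in enumerate(spec.points):
        lev = point_labels.iloc[i]
        p.color_key = lev
        p.shape_key = lev
    legend = {f"{ray_variable}:{g}": g for g in c.group_labels}
    legend.update({f"{point_variable}:{lev}": lev for lev in sorted(point_styles)})
    spec.legend = legend
    return spec


def render(spec: PlotSpec, path: str | Path, format: str | None = None) -> Path:
    """Render a spec to PNG/SVG/PDF; deterministic given (spec, format)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("png", "svg", "pdf"):
        raise ValueError(f"unknown image format {fmt!r}")
    with matplotlib.rc_context({"svg.hashsalt": "batchray"}):
        fig, ax = plt.subplots(figsize=(7, 6))
        ray_styles = assign_styles([c.group for c in spec.centroids])
        point_levels = sorted({p.color_key for p in spec.points})
        point_styles = assign_styles(point_levels)
        for ray in spec.rays:
            color = ray_styles[ray.color_key][0]
            ax.plot([ray.x0, ray.x1], [ray.y0, ray.y1],
                    color=color, linewidth=0.6, alpha=0.5, zorder=1)
        for lev in point_levels:
            color, marker = point_styles[lev]
            xs = [p.x for p in spec.points if p.color_key == lev]
            ys = [p.y for p in spec.points if p.color_key == lev]
            ax.scatter(xs, ys, s=18, color=color, marker=marker,
                       label=lev, zorder=2, edgecolors="none")
        for cen in spec.centroids:
            color = ray_styles[cen.color_key][0]
            ax.scatter([cen.x], [cen.y], s=120, color=color, marker="D",
                       edgecolors="black", linewidths=0.8, zorder=3)
        for arrow in spec.arrows:
            ax.annotate(
                "", xy=(arrow.x1, arrow.y1), xytext=(arrow.x0, arrow.y0),
                arrowprops=dict(arrowstyle="->", color="black", lw=1.2),
                zorder=4,
            )
        ax.set_xlabel(spec.axis_labels[0])
        ax.set_ylabel(spec.axis_labels[1])
        if spec.subtitle:
            ax.set_title(spec.subtitle, fontsize=9)
        ax.legend(loc="best", fontsize=7, frameon=False)
        fig.tight_layout()
        if fmt == "svg":
            metadata = {"Date": None}
        elif fmt == "pdf":
            metadata = {"CreationDate": None}
        else:
            metadata = None
        fig.savefig(path, format=fmt, metadata=metadata, dpi=150)
        plt.close(fig)
    return path
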
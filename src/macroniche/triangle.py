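"""Mixture-triangle geometry and deterministic SVG rendering.

A 3-part composition can be drawn in an equilateral mixture triangle (EMT,
the conventional ternary diagram: each corner is 100% of one part) or in a
right-angled mixture triangle (RMT: two parts on the axes, the third
implicit). Overlays cover the study's figure vocabulary: isoportion lines
(one part held at a fixed fraction, e.g. the 17% protein intake target with
its +/-4 band), 1:1 isoproportion lines radiating from the opposite corner,
sigma/confidence region boundaries, and curvilinear acomp-PCA axes, which
are straight lines in ilr coordinates and curves in the EMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compositional import (
    Composition,
    CompositionSet,
    PcaResult,
    SimplexRegion,
    clr,
    clr_inv,
    closure,
)

__all__ = [
    "emt_coords",
    "emt_inverse",
    "rmt_coords",
    "isoportion_line",
    "isoproportion_line",
    "pca_axis_curve",
    "Scene",
    "render",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0

#: Default corner order: first part bottom-left, second bottom-right, third top.
DEFAULT_CORNERS = ("P", "C", "L")


def _ordered_values(c: Composition, corner_order: Sequence[str]) -> np.ndarray:
    if set(corner_order) != set(c.parts) or len(corner_order) != 3:
        raise ValueError(
            f"corner order {corner_order!r} does not match parts {c.parts!r}"
        )
    return np.array([c[p] for p in corner_order])


def emt_coords(
    c: Composition, corner_order: Sequence[str] = DEFAULT_CORNERS
) -> tuple[float, float]:
    """Equilateral-triangle coordinates: x = c2 + c3/2, y = (sqrt3/2) c3.

    Corners map to (0,0), (1,0) and (1/2, sqrt3/2); the mapping is affine in
    the composition, so the barycentre lands on the centroid.
    """
    c1, c2, c3 = _ordered_values(c, corner_order)
    return float(c2 + c3 / 2.0), float(_SQRT3_2 * c3)


def emt_inverse(
    xy: tuple[float, float], corner_order: Sequence[str] = DEFAULT_CORNERS
) -> Composition:
    """Invert emt_coords back to the composition (exact, affine)."""
    x, y = xy
    c3 = y / _SQRT3_2
    c2 = x - c3 / 2.0
    c1 = 1.0 - c2 - c3
    vals = {p: v for p, v in zip(corner_order, (c1, c2, c3))}
    order = sorted(corner_order, key=list(corner_order).index)
    # re-emit in the composition's canonical (P,C,L) part order
    return Composition(tuple(corner_order), np.array([vals[p] for p in corner_order]))


def rmt_coords(c: Composition, axes: tuple[str, str]) -> tuple[float, float]:
    """Right-angled mixture triangle: the two chosen parts, third implicit."""
    a, b = axes
    if a == b or a not in c.parts or b not in c.parts:
        raise ValueError(f"RMT axes must be two distinct parts of {c.parts!r}")
    return c[a], c[b]


def isoportion_line(
    part: str, value: float, parts: Sequence[str] = DEFAULT_CORNERS
) -> tuple[Composition, Composition]:
    """Endpoints of the locus {compositions with `part` = value}.

    The locus is the chord parallel to the edge opposite the part's corner;
    its endpoints put the whole remainder 1-value on one of the other parts.
    """
    if not 0 < value < 1:
        raise ValueError("isoportion value must be strictly inside (0,1)")
    others = [p for p in parts if p != part]
    if len(others) != 2:
        raise ValueError(f"part {part!r} not among {parts!r}")
    end = []
    for other in others:
        vals = {p: 0.0 for p in parts}
        vals[part] = value
        vals[other] = 1.0 - value
        end.append(Composition(tuple(parts), np.array([vals[p] for p in parts])))
    return end[0], end[1]


def isoproportion_line(
    pair: tuple[str, str], parts: Sequence[str] = DEFAULT_CORNERS
) -> tuple[Composition, Composition]:
    """The 1:1 line {c_i = c_j}: from the third part's corner to the
    midpoint of the opposite edge."""
    i, j = pair
    if i == j:
        raise ValueError("isoproportion pair must be two distinct parts")
    third = [p for p in parts if p not in pair]
    if len(third) != 1:
        raise ValueError(f"pair {pair!r} not among {parts!r}")
    corner = {p: 0.0 for p in parts}
    corner[third[0]] = 1.0
    mid = {p: 0.5 for p in pair}
    mid[third[0]] = 0.0
    mk = lambda d: Composition(tuple(parts), np.array([d[p] for p in parts]))
    return mk(corner), mk(mid)


def pca_axis_curve(
    p: PcaResult, component: int, span: tuple[float, float], n_points: int = 101
) -> CompositionSet:
    """Aitchison geodesic center (+) t*direction, sampled over span.

    Straight in clr/ilr coordinates; curvilinear when drawn in the EMT.
    """
    if not 1 <= component <= p.components.shape[0]:
        raise ValueError(f"component must be 1..{p.components.shape[0]}")
    lo, hi = span
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("span must be finite")
    direction = p.components[component - 1]
    c0 = clr(p.center)
    ts = np.linspace(lo, hi, n_points)
    rows = np.stack([clr_inv(c0 + t * direction, p.center.parts).values for t in ts])
    return CompositionSet(p.center.parts, rows)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class Scene:
    """Everything to draw in one mixture triangle."""

    points: CompositionSet | None = None
    means: list[tuple[str, Composition]] = field(default_factory=list)
    regions: list[SimplexRegion] = field(default_factory=list)
    lines: list[tuple[str, Composition, Composition]] = field(default_factory=list)
    curves: list[CompositionSet] = field(default_factory=list)
    pca: PcaResult | None = None
    corner_order: tuple[str, str, str] = DEFAULT_CORNERS

    def _all_parts(self):
        out = []
        if self.points is not None:
            out.append(self.points.parts)
        out += [c.parts for _, c in self.means]
        out += [r.boundary.parts for r in self.regions]
        out += [a.parts for _, a, _ in self.lines]
        out += [c.parts for c in self.curves]
        if self.pca is not None:
            out.append(self.pca.center.parts)
        return out


DEFAULT_STYLE = {
    "point_color": "black",
    "mean_color": "red",
    "sigma_colors": {2.0: "blue", 3.0: "red"},
    "confidence_colors": {0.90: "blue", 0.99: "red"},
    "target_color": "blue",
    "line_color": "black",
    "curve_color": "green",
}


def render(
    scene: Scene,
    path: str,
    mode: str = "emt",
    rmt_axes: tuple[str, str] = ("C", "L"),
    style: dict | None = None,
) -> str:
    """Render a scene to a deterministic SVG file.

    Identical scene + style always yields byte-identical SVG (fixed hash
    salt, no timestamps). Returns the output path.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    parts_seen = scene._all_parts()
    if len({p for p in parts_seen}) > 1:
        raise ValueError(f"scene mixes part orders: {sorted(set(parts_seen))}")
    sty = {**DEFAULT_STYLE, **(style or {})}
    order = scene.corner_order

    if mode == "emt":
        to_xy = lambda c: emt_coords(c, order)
        frame = [(0, 0), (1, 0), (0.5, _SQRT3_2), (0, 0)]
        labels = [(order[0], (-0.03, -0.04)), (order[1], (1.03, -0.04)),
                  (order[2], (0.5, _SQRT3_2 + 0.03))]
    elif mode == "rmt":
        to_xy = lambda c: rmt_coords(c, rmt_axes)
        frame = [(0, 0), (1, 0), (0, 1), (0, 0)]
        labels = [(rmt_axes[0], (1.02, -0.02)), (rmt_axes[1], (-0.02, 1.02))]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    with plt.rc_context({"svg.hashsalt": "macroniche"}):
        fig, ax = plt.subplots(figsize=(5, 5))
        fx, fy = zip(*frame)
        ax.plot(fx, fy, color="black", lw=1)
        for text, (x, y) in labels:
            ax.text(x, y, text, ha="center", va="center")
        for name, a, b in scene.lines:
            (x0, y0), (x1, y1) = to_xy(a), to_xy(b)
            color = sty["target_color"] if name.startswith("target") else sty["line_color"]
            lw = 0.8 if name.endswith("band") else 1.2
            ax.plot([x0, x1], [y0, y1], color=color, lw=lw,
                    linestyle="--" if name.endswith("band") else "-")
        for reg in scene.regions:
            xy = np.array([to_xy(c) for c in reg.boundary])
            cmap = sty["sigma_colors"] if reg.kind == "sigma" else sty["confidence_colors"]
            ax.plot(xy[:, 0], xy[:, 1], color=cmap.get(reg.level, "gray"), lw=1)
        for curve in scene.curves:
            xy = np.array([to_xy(c) for c in curve])
            ax.plot(xy[:, 0], xy[:, 1], color=sty["curve_color"], lw=1)
        if scene.points is not None:
            xy = np.array([to_xy(c) for c in scene.points])
            ax.scatter(xy[:, 0], xy[:, 1], s=14, color=sty["point_color"], zorder=3)
        for name, mean in scene.means:
            x, y = to_xy(mean)
            ax.scatter([x], [y], marker="^", s=40, color=sty["mean_color"], zorder=4)
        if scene.pca is not None:
            for comp in range(1, scene.pca.components.shape[0] + 1):
                sd = np.sqrt(scene.pca.explained_variance[comp - 1])
                curve = pca_axis_curve(scene.pca, comp, (-2.5 * sd, 2.5 * sd))
                xy = np.array([to_xy(c) for c in curve])
                ax.plot(xy[:, 0], xy[:, 1], color=sty["curve_color"], lw=1)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
    return path


def biplot(p: PcaResult, path: str, labels: Sequence[str] | None = None) -> str:
    """Covariance biplot of an acomp PCA: scores plus clr loading rays.

    The link between two ray tips approximates the SD of the corresponding
    pairwise log-ratio (exact for 3 parts when both components are drawn).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    with plt.rc_context({"svg.hashsalt": "macroniche"}):
        fig, ax = plt.subplots(figsize=(5, 5))
        sc = p.scores
        ax.scatter(sc[:, 0], sc[:, 1], s=12, color="black")
        if labels is not None:
            for (x, y), lab in zip(sc[:, :2], labels):
                ax.annotate(str(lab), (x, y), fontsize=7,
                            xytext=(2, 2), textcoords="offset points")
        for part, ray in zip(p.center.parts, p.biplot_rays):
            ax.annotate(
                "", xy=(ray[0], ray[1]), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="red"),
            )
            ax.annotate(part, (ray[0], ray[1]), color="red",
                        xytext=(3, 3), textcoords="offset points")
        share = p.explained_shares
        ax.set_xlabel(f"Component 1 ({100 * share[0]:.1f}%)")
        ax.set_ylabel(f"Component 2 ({100 * share[1]:.1f}%)")
        ax.axhline(0, color="gray", lw=0.5)
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_aspect("equal")
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
    return path
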
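"""Node-distance ancestry chronologies and evolutionary heat maps.

On an intrinsically rooted tree of substructures, the relative age of each
leaf is measured by counting internal nodes on the path from the root to the
leaf and normalising to a 0-1 scale: nd = (d - 1)/(d_max - 1), so the most
basal leaf (the oldest substructure) scores exactly 0 and the deepest scores
1.  A star tree (d_max = 1) scores 0 everywhere.  Polytomy nodes count once,
so ties in a consensus tree share nd values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AncestryMap",
    "node_distance",
    "cumulative_accretion",
    "render_heatmap",
]


@dataclass
class AncestryMap:
    """Leaf -> nd value on a 0-1 scale, plus binned colour classes."""

    nd: dict[str, float]
    n_bins: int = 10

    def __post_init__(self) -> None:
        for leaf, v in self.nd.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"nd[{leaf!r}] = {v} outside [0, 1]")

    def bin_of(self, leaf: str) -> int:
        """Colour class index in 0..n_bins-1 (nd = 1 falls in the last bin)."""
        return min(int(self.nd[leaf] * self.n_bins), self.n_bins - 1)

    @property
    def bin_boundaries(self) -> list[float]:
        return [k / self.n_bins for k in range(1, self.n_bins)]

    def to_tsv(self) -> str:
        lines = ["label\tnd"]
        for leaf, v in sorted(self.nd.items(), key=lambda kv: (kv[1], kv[0])):
            lines.append(f"{leaf}\t{v:.2f}")
        return "\n".join(lines) + "\n"


def node_distance(tree: dendropy.Tree, n_bins: int = 10) -> AncestryMap:
    """Node-distance ancestry of every leaf of a rooted tree.

    The depth d of a leaf counts the internal nodes on its root path (the
    root included), and nd = (d - d_min)/(d_max - d_min), so the basal-most
    leaf scores exactly 0 and the deepest exactly 1.  On trees whose basal
    leaf attaches at the root (d_min = 1) this equals (d - 1)/(d_max - 1).
    """
    if not tree.is_rooted:
        raise ValueError("node distances require a rooted tree")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    depth: dict[str, int] = {}
    for leaf in leaves:
        d = 0
        node = leaf.parent_node
        while node is not None:
            d += 1
            node = node.parent_node
        depth[leaf.taxon.label] = d
    d_max = max(depth.values())
    d_min = min(depth.values())
    if d_max == d_min:  # star tree: no chronology
        nd = {k: 0.0 for k in depth}
    else:
        nd = {k: (d - d_min) / (d_max - d_min) for k, d in depth.items()}
    return AncestryMap(nd, n_bins=n_bins)


def cumulative_accretion(
    amap: AncestryMap, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Cumulative counts of leaves per group along the nd timeline.

    Returns a frame indexed by the distinct nd values with one nondecreasing
    column per group; the value at nd = max equals the group size.
    """
    groups = groups or {leaf: "all" for leaf in amap.nd}
    names = sorted(set(groups.values()))
    xs = sorted(set(amap.nd.values()))
    data = {}
    for g in names:
        members = [v for leaf, v in amap.nd.items() if groups.get(leaf) == g]
        data[g] = [sum(1 for v in members if v <= x) for x in xs]
    return pd.DataFrame(data, index=pd.Index(xs, name="nd"))


# ---------------------------------------------------------------------------
# heat maps


_GREY = "#b0b0b0"


def _bin_colors(n_bins: int, cmap_name: str = "RdYlBu_r") -> list[str]:
    from matplotlib import colormaps
    from matplotlib.colors import to_hex

    cmap = colormaps[cmap_name]
    return [to_hex(cmap((k + 0.5) / n_bins)) for k in range(n_bins)]


def _heatmap_from_layout(
    amap: AncestryMap, layout: list[tuple[str, float, float, str]],
    colors: list[str],
) -> str:
    """Render a TSV layout (label, x, y, shape) as an SVG document."""
    cell = 40.0
    missing: list[str] = []
    parts: list[str] = []
    max_x = max((x for _, x, _, _ in layout), default=0) + 2
    max_y = max((y for _, _, y, _ in layout), default=0) + 3
    width = max(max_x * cell, 340.0)
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{(max_y + 1.2) * cell:.0f}">'
    )
    for label, x, y, shape in layout:
        if label in amap.nd:
            fill = colors[amap.bin_of(label)]
        else:
            fill = _GREY
            missing.append(label)
        cx, cy = (x + 0.5) * cell, (y + 0.5) * cell
        if shape == "circle":
            parts.append(
                f'<circle id="{label}" cx="{cx:.1f}" cy="{cy:.1f}" '
                f'r="{cell * 0.42:.1f}" fill="{fill}" stroke="black"/>'
            )
        else:
            parts.append(
                f'<rect id="{label}" x="{x * cell + 2:.1f}" y="{y * cell + 2:.1f}" '
                f'width="{cell - 4:.1f}" height="{cell - 4:.1f}" '
                f'fill="{fill}" stroke="black"/>'
            )
        parts.append(
            f'<text x="{cx:.1f}" y="{cy + 4:.1f}" font-size="11" '
            f'text-anchor="middle">{label}</text>'
        )
    parts.append(_legend_svg(amap, colors, y_px=max_y * cell))
    if missing:
        parts.append(
            f"<!-- warning: no nd value for: {', '.join(sorted(missing))} -->"
        )
        warnings.warn(
            f"template labels without nd values rendered grey: {sorted(missing)}",
            stacklevel=3,
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _legend_svg(amap: AncestryMap, colors: list[str], y_px: float) -> str:
    parts = [f'<g id="legend" transform="translate(10,{y_px:.0f})">']
    step = 30.0
    bounds = [0.0] + amap.bin_boundaries + [1.0]
    for k, c in enumerate(colors):
        parts.append(
            f'<rect x="{k * step:.0f}" y="0" width="{step:.0f}" height="14" '
            f'fill="{c}" stroke="black"/>'
        )
        parts.append(
            f'<text x="{k * step:.0f}" y="28" font-size="9">{bounds[k]:.1f}</text>'
        )
    parts.append(
        f'<text x="{len(colors) * step:.0f}" y="28" font-size="9">1.0</text>'
    )
    parts.append('<text x="0" y="44" font-size="11">ancestry (nd), old to new</text>')
    parts.append("</g>")
    return parts and "\n".join(parts)


def _heatmap_from_svg_template(
    amap: AncestryMap, template: str, colors: list[str]
) -> str:
    """Fill an SVG template whose elements carry substructure ``id``s."""
    from lxml import etree

    root = etree.fromstring(template.encode())
    missing: list[str] = []
    seen = set()
    for el in root.iter():
        label = el.get("id")
        if not label or label in ("legend",):
            continue
        seen.add(label)
        if label in amap.nd:
            el.set("fill", colors[amap.bin_of(label)])
        else:
            el.set("fill", _GREY)
            missing.append(label)
    if missing:
        root.append(
            etree.Comment(
                f" warning: no nd value for: {', '.join(sorted(missing))} "
            )
        )
        warnings.warn(
            f"template labels without nd values rendered grey: {sorted(missing)}",
            stacklevel=3,
        )
    return etree.tostring(root, pretty_print=True).decode()


def render_heatmap(
    amap: AncestryMap,
    template: str,
    template_format: str = "tsv",
    cmap: str = "RdYlBu_r",
) -> str:
    """Colour a secondary-structure layout by ancestry class.

    ``template`` is either a TSV layout (``label<TAB>x<TAB>y<TAB>shape``
    rows, shape in {circle, rect}) or an SVG document whose paintable
    elements carry ``id`` attributes equal to substructure labels.  Elements
    without an nd value are rendered grey and listed in a warning comment.
    Returns an SVG 1.1 document.
    """
    colors = _bin_colors(amap.n_bins, cmap)
    if template_format == "svg":
        return _heatmap_from_svg_template(amap, template, colors)
    if template_format != "tsv":
        raise ValueError(f"unknown template format {template_format!r}")
    layout = []
    for ln_no, raw in enumerate(template.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"template line {ln_no}: expected 4 fields")
        label, x, y, shape = fields
        layout.append((label, float(x), float(y), shape))
    return _heatmap_from_layout(amap, layout, colors)
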
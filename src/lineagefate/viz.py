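"""Lineage-tree rendering as SVG.

Conventions follow the live-cell figures of the study system: time runs
left to right (hours), each cell cycle is a horizontal gray bar, mitosis
a green bar ending in a bifurcation (trifurcation after tripolar
mitosis), micronucleus and bi/multi-nuclei symbols sit at the start of
the affected cycle, death and fading symbols at the end of the observed
segment, and sister-cell fusions are drawn as blue connectors between
the fusing branches.

SVG is emitted by a small built-in XML builder; the symbol glyphs and
colors live in :class:`TreeStyle` and can be restyled.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field, replace
from pathlib import Path

from .trees import LineageTree

__all__ = ["TreeStyle", "TreeFigure", "render_tree", "render_gallery"]


@dataclass(frozen=True)
class TreeStyle:
    px_per_hour: float = 8.0
    row_height: float = 16.0
    bar_width: float = 4.0
    margin: float = 30.0
    default_tail: float = 1.0  # hours drawn for cells with no timing info
    movie_end: float | None = None  # right edge for censored cells
    interphase_color: str = "#9e9e9e"
    mitosis_color: str = "#2e9e46"
    fusion_color: str = "#2060c8"
    mn_color: str = "#d02020"
    death_color: str = "#8030a0"
    bi_multi_color: str = "#e08020"
    fading_color: str = "#c0c0c0"
    regression_color: str = "#806020"
    show_legend: bool = True
    time_axis: bool = True


@dataclass
class TreeFigure:
    svg: str
    n_segments: int
    n_bifurcations: int
    symbol_counts: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.svg, encoding="utf-8")


def _esc(s: str) -> str:
    return html.escape(str(s), quote=True)


class _Svg:
    def __init__(self) -> None:
        self.parts: list[str] = []

    def line(self, x1, y1, x2, y2, color, width=1.5, dash: str | None = None) -> None:
        d = f' stroke-dasharray="{dash}"' if dash else ""
        self.parts.append(
            f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" y2="{y2:.2f}" '
            f'stroke="{color}" stroke-width="{width}"{d}/>'
        )

    def rect(self, x, y, w, h, color, fill=True) -> None:
        style = f'fill="{color}"' if fill else f'fill="none" stroke="{color}"'
        self.parts.append(f'<rect x="{x:.2f}" y="{y:.2f}" width="{w:.2f}" height="{h:.2f}" {style}/>')

    def circle(self, cx, cy, r, color, fill=False) -> None:
        style = f'fill="{color}"' if fill else f'fill="none" stroke="{color}" stroke-width="1.5"'
        self.parts.append(f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{r:.2f}" {style}/>')

    def text(self, x, y, s, size=10, color="#303030") -> None:
        self.parts.append(
            f'<text x="{x:.2f}" y="{y:.2f}" font-size="{size}" '
            f'font-family="Helvetica,Arial,sans-serif" fill="{color}">{_esc(s)}</text>'
        )

    def document(self, width: float, height: float) -> str:
        body = "\n".join(self.parts)
        return (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
            f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">\n'
            f"{body}\n</svg>\n"
        )


def _leaf_order(tree: LineageTree) -> list[str]:
    order: list[str] = []

    def walk(cid: str) -> None:
        kids = tree.children.get(cid, [])
        if not kids:
            order.append(cid)
        for k in kids:
            walk(k)

    walk(tree.root.cell_id)
    return order


def _segment_end(tree: LineageTree, cid: str, style: TreeStyle) -> float:
    r = tree.cells[cid]
    if r.t_division is not None:
        return r.t_division
    if r.censored and style.movie_end is not None:
        return max(style.movie_end, r.t_birth)
    if r.t_nebd is not None:
        return r.t_nebd
    return r.t_birth + style.default_tail


def _draw_symbol(svg: _Svg, kind: str, x: float, y: float, style: TreeStyle) -> None:
    r = 4.0
    if kind == "mn":  # red cross
        svg.line(x - r, y - r, x + r, y + r, style.mn_color, 1.8)
        svg.line(x - r, y + r, x + r, y - r, style.mn_color, 1.8)
    elif kind == "bi_multi":  # two nested circles
        svg.circle(x, y, r, style.bi_multi_color)
        svg.circle(x, y, r / 2, style.bi_multi_color)
    elif kind == "death":  # filled square
        svg.rect(x - r, y - r, 2 * r, 2 * r, style.death_color)
    elif kind == "fading":  # open triangle
        svg.parts.append(
            f'<polygon points="{x - r:.2f},{y + r:.2f} {x + r:.2f},{y + r:.2f} {x:.2f},{y - r:.2f}" '
            f'fill="none" stroke="{style.fading_color}" stroke-width="1.5"/>'
        )
    elif kind == "regression":  # open diamond
        svg.parts.append(
            f'<polygon points="{x - r:.2f},{y:.2f} {x:.2f},{y - r:.2f} {x + r:.2f},{y:.2f} {x:.2f},{y + r:.2f}" '
            f'fill="none" stroke="{style.regression_color}" stroke-width="1.5"/>'
        )


_LEGEND = (
    ("mn", "micronucleus"),
    ("bi_multi", "bi/multi-nuclei"),
    ("death", "cell death"),
    ("fading", "mCitrine fading"),
    ("regression", "furrow regression"),
)


def render_tree(tree: LineageTree, style: TreeStyle | None = None) -> TreeFigure:
    """Render one lineage tree; deterministic for a fixed input."""
    style = style or TreeStyle()
    if style.movie_end is None:
        last = max(_segment_end(tree, cid, replace(style, movie_end=0.0)) for cid in tree.cells)
        style = replace(style, movie_end=last)

    leaves = _leaf_order(tree)
    ypos: dict[str, float] = {}
    for i, leaf in enumerate(leaves):
        ypos[leaf] = style.margin + i * style.row_height

    def assign(cid: str) -> float:
        if cid in ypos:
            return ypos[cid]
        ys = [assign(k) for k in tree.children[cid]]
        ypos[cid] = sum(ys) / len(ys)
        return ypos[cid]

    assign(tree.root.cell_id)

    svg = _Svg()
    x0 = style.margin

    def px(t: float) -> float:
        return x0 + t * style.px_per_hour

    counts: dict[str, int] = {k: 0 for k, _ in _LEGEND}
    n_bif = 0
    for cid in sorted(tree.cells):
        r = tree.cells[cid]
        y = ypos[cid]
        end = _segment_end(tree, cid, style)
        inter_end = r.t_nebd if r.t_nebd is not None else end
        svg.line(px(r.t_birth), y, px(inter_end), y, style.interphase_color, style.bar_width)
        if r.t_nebd is not None:
            svg.line(px(r.t_nebd), y, px(end), y, style.mitosis_color, style.bar_width)
        kids = tree.children.get(cid, [])
        if kids and r.t_division is not None:
            n_bif += 1
            ys = [ypos[k] for k in kids]
            svg.line(px(r.t_division), min(ys), px(r.t_division), max(ys),
                     style.interphase_color, 1.5)
        if r.micronuclei:
            _draw_symbol(svg, "mn", px(r.t_birth), y, style)
            counts["mn"] += 1
        if r.bi_multi_nuclei:
            _draw_symbol(svg, "bi_multi", px(r.t_birth), y - 7, style)
            counts["bi_multi"] += 1
        if r.death:
            _draw_symbol(svg, "death", px(end), y, style)
            counts["death"] += 1
        if r.fading:
            _draw_symbol(svg, "fading", px(end), y, style)
            counts["fading"] += 1
        if r.regression:
            _draw_symbol(svg, "regression", px(end), y, style)
            counts["regression"] += 1

    for a, b in tree.fusion_links:
        ta = tree.cells[a].t_birth
        svg.line(px(ta), ypos[a], px(ta), ypos[b], style.fusion_color, 2.0, dash="4,3")

    height = style.margin + len(leaves) * style.row_height + 30
    width = px(style.movie_end) + style.margin

    if style.time_axis:
        axis_y = height - 18
        svg.line(px(0), axis_y, px(style.movie_end), axis_y, "#303030", 1.0)
        tick = 12
        t = 0.0
        while t <= style.movie_end + 1e-9:
            svg.line(px(t), axis_y, px(t), axis_y + 4, "#303030", 1.0)
            svg.text(px(t) - 6, axis_y + 14, f"{t:.0f}", size=8)
            t += tick
        svg.text(px(style.movie_end) + 6, axis_y + 4, "h", size=9)
    svg.text(x0, 14, f"lineage {tree.lineage_id}", size=10)

    if style.show_legend:
        lx = x0
        ly = 24.0
        for kind, label in _LEGEND:
            _draw_symbol(svg, kind, lx, ly - 3, style)
            svg.text(lx + 8, ly, label, size=8)
            lx += 110

    return TreeFigure(
        svg=svg.document(width, height),
        n_segments=len(tree.cells),
        n_bifurcations=n_bif,
        symbol_counts=counts,
    )


def render_gallery(
    trees: list[LineageTree], directory: str | Path, style: TreeStyle | None = None
) -> list[Path]:
    """Write one SVG per tree, grouped into per-condition subdirectories
    (the layout of the study's supplementary tree panels)."""
    directory = Path(directory)
    written: list[Path] = []
    for tree in sorted(trees, key=lambda t: (t.condition, t.lineage_id)):
        cond = "_".join(tree.condition).replace("+", "").replace("/", "-")
        sub = directory / cond
        sub.mkdir(parents=True, exist_ok=True)
        fig = render_tree(tree, style)
        path = sub / f"{tree.lineage_id}.svg"
        fig.save(path)
        written.append(path)
    return written
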
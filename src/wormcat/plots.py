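"""Deterministic SVG rendering of enrichment results.

Two figure styles, both emitted as plain SVG 1.1 text with fixed viewBox and
font metrics so identical inputs always produce byte-identical documents:

* scaled bubble chart — one circle per (dataset, significant category), circle
  AREA proportional to the number of RGS genes in the category, fill color
  encoding the adjusted-p significance bin; categories stacked on the vertical
  axis ordered by their best p across datasets, datasets side by side in input
  order.  Useful for comparing many conditions at once.
* sunburst — three concentric rings (Cat1 innermost, Cat3 outermost) showing
  the nested category composition of the mapped gene set; each arc's angular
  span is its share of its parent's span, so child arcs nest exactly inside
  their parent and every ring closes to 360 degrees.

Every arc and circle carries ``data-`` attributes (category, count, angles)
so documents are machine-checkable as well as viewable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .annotation import CategoryPath
from .enrichment import EnrichmentResult, EnrichmentRow

__all__ = ["PlotConfig", "bubble_chart_svg", "sunburst_svg"]

# colorblind-safe blues, darkest = most significant
BIN_COLORS = ("#9ecae1", "#4292c6", "#084594")
NOT_SIG_GRAY = "#cccccc"


@dataclass
class PlotConfig:
    """Rendering knobs shared by both figure styles.

    ``significance_bins`` are adjusted-p cutoffs, strictly decreasing; a row's
    fill is the color of the smallest cutoff it clears.  ``bubble_scale`` is
    the circle area (square user units) contributed by each RGS gene.
    ``size_by`` chooses whether bubble area tracks the raw RGS gene count or
    the percentage of the category captured by the RGS.
    """

    significance_bins: tuple[float, ...] = (0.05, 0.01, 0.001)
    bubble_scale: float = 12.0
    level: int = 1
    max_categories: int = 40
    size_by: str = "count"  # or "percent"

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.significance_bins) or list(
            self.significance_bins
        ) != sorted(self.significance_bins, reverse=True):
            raise ValueError("significance bins must be positive and strictly decreasing")
        if self.bubble_scale <= 0:
            raise ValueError("bubble scale must be positive")
        if self.size_by not in ("count", "percent"):
            raise ValueError("size_by must be 'count' or 'percent'")

    def bin_color(self, p_adjusted: float) -> str:
        color = NOT_SIG_GRAY
        for cutoff, c in zip(self.significance_bins, BIN_COLORS):
            if p_adjusted < cutoff:
                color = c
        return color


def _fmt(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".")


def _esc(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")


def _svg_doc(width: float, height: float, body: list[str]) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" font-family="Helvetica, Arial, sans-serif">\n'
    )
    return head + "".join(line + "\n" for line in body) + "</svg>\n"


def _legend(cfg: PlotConfig, x: float, y: float) -> list[str]:
    out = [f'<g data-role="legend" transform="translate({_fmt(x)},{_fmt(y)})">']
    for i, (cutoff, color) in enumerate(zip(cfg.significance_bins, BIN_COLORS)):
        yy = i * 18
        out.append(
            f'<rect x="0" y="{_fmt(yy)}" width="12" height="12" fill="{color}"/>'
            f'<text x="18" y="{_fmt(yy + 10)}" font-size="11">adj p &lt; {_fmt(cutoff)}</text>'
        )
    out.append("</g>")
    return out


def bubble_chart_svg(
    results: EnrichmentResult | Sequence[EnrichmentResult],
    cfg: PlotConfig | None = None,
) -> str:
    """Render one or more enrichment results as a scaled bubble chart.

    Only significant rows at ``cfg.level`` are drawn (the CSVs keep
    everything).  With no significant category anywhere the document still
    renders — legend plus a notice — with zero circles.
    """
    cfg = cfg or PlotConfig()
    if isinstance(results, EnrichmentResult):
        results = [results]
    results = list(results)
    if not results:
        raise ValueError("at least one enrichment result is required")

    sig: dict[CategoryPath, float] = {}
    per_dataset: list[dict[CategoryPath, EnrichmentRow]] = []
    for res in results:
        rows = {r.category: r for r in res.significant_rows(cfg.level)}
        per_dataset.append(rows)
        for cat, row in rows.items():
            sig[cat] = min(sig.get(cat, 1.0), row.p)
    cats = sorted(sig, key=lambda c: (sig[c], c.as_tuple()))[: cfg.max_categories]

    row_h = 26.0
    col_w = 90.0
    label_w = 260.0
    top = 50.0
    width = label_w + col_w * max(len(results), 1) + 170.0
    height = top + row_h * max(len(cats), 1) + 80.0
    body: list[str] = []

    for j, res in enumerate(results):
        x = label_w + col_w * (j + 0.5)
        body.append(
            f'<text x="{_fmt(x)}" y="30" font-size="12" text-anchor="middle" '
            f'data-role="dataset-label">{_esc(res.rgs.name)}</text>'
        )
    if not cats:
        body.append(
            f'<text x="{_fmt(label_w)}" y="{_fmt(top + 20)}" font-size="12" '
            'data-role="notice">no significant categories at this level</text>'
        )
    for i, cat in enumerate(cats):
        y = top + row_h * (i + 0.5)
        body.append(
            f'<text x="{_fmt(label_w - 10)}" y="{_fmt(y + 4)}" font-size="11" '
            f'text-anchor="end" data-role="category-label">{_esc(cat.label)}</text>'
        )
        for j, rows in enumerate(per_dataset):
            row = rows.get(cat)
            if row is None:
                continue
            size = (
                row.rgs_count
                if cfg.size_by == "count"
                else 100.0 * row.rgs_count / row.universe_count
            )
            r = math.sqrt(cfg.bubble_scale * size / math.pi)
            x = label_w + col_w * (j + 0.5)
            body.append(
                f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(r)}" '
                f'fill="{cfg.bin_color(row.p_adjusted)}" fill-opacity="0.85" '
                f'data-dataset="{_esc(results[j].rgs.name)}" '
                f'data-category="{_esc(cat.label)}" data-count="{row.rgs_count}" '
                f'data-p-adjusted="{row.p_adjusted:.6g}"/>'
            )
    body.extend(_legend(cfg, label_w + col_w * len(results) + 20.0, top))
    return _svg_doc(width, height, body)


def _arc_path(cx: float, cy: float, r0: float, r1: float, a0: float, a1: float) -> str:
    """Annular-sector path; angles in degrees, 0 at 12 o'clock, clockwise."""
    span = a1 - a0
    if span >= 360.0 - 1e-9:
        # full ring: two half arcs per radius
        return (
            f"M {_fmt(cx)} {_fmt(cy - r1)} "
            f"A {_fmt(r1)} {_fmt(r1)} 0 1 1 {_fmt(cx)} {_fmt(cy + r1)} "
            f"A {_fmt(r1)} {_fmt(r1)} 0 1 1 {_fmt(cx)} {_fmt(cy - r1)} Z "
            f"M {_fmt(cx)} {_fmt(cy - r0)} "
            f"A {_fmt(r0)} {_fmt(r0)} 0 1 0 {_fmt(cx)} {_fmt(cy + r0)} "
            f"A {_fmt(r0)} {_fmt(r0)} 0 1 0 {_fmt(cx)} {_fmt(cy - r0)} Z"
        )

    def pt(r: float, a: float) -> tuple[float, float]:
        rad = math.radians(a - 90.0)
        return cx + r * math.cos(rad), cy + r * math.sin(rad)

    large = 1 if span > 180.0 else 0
    x0o, y0o = pt(r1, a0)
    x1o, y1o = pt(r1, a1)
    x1i, y1i = pt(r0, a1)
    x0i, y0i = pt(r0, a0)
    return (
        f"M {_fmt(x0o)} {_fmt(y0o)} "
        f"A {_fmt(r1)} {_fmt(r1)} 0 {large} 1 {_fmt(x1o)} {_fmt(y1o)} "
        f"L {_fmt(x1i)} {_fmt(y1i)} "
        f"A {_fmt(r0)} {_fmt(r0)} 0 {large} 0 {_fmt(x0i)} {_fmt(y0i)} Z"
    )


_RING_PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02",
    "#a6761d", "#666666", "#1f78b4", "#b2df8a", "#fb9a99", "#fdbf6f",
)


def sunburst_svg(result: EnrichmentResult, cfg: PlotConfig | None = None) -> str:
    """Render the nested category composition of a mapped gene set.

    Angular spans: a Cat1 arc covers its share of the mapped genes carrying a
    Cat1 label; a child arc covers ``parent span * child count / parent
    count``, so child arcs nest exactly inside their parent.  Genes whose path
    stops before the outer ring leave a neutral filler arc in their parent's
    remaining span, so every ring closes to 360 degrees.
    """
    cfg = cfg or PlotConfig()
    counts: dict[int, dict[CategoryPath, int]] = {1: {}, 2: {}, 3: {}}
    for level in (1, 2, 3):
        for row in result.rows[level]:
            if row.rgs_count > 0:
                counts[level][row.category] = row.rgs_count

    cx = cy = 320.0
    radii = (40.0, 110.0, 180.0, 250.0)  # ring boundaries, Cat1 = innermost ring
    body: list[str] = []
    total1 = sum(counts[1].values())
    if total1 == 0:
        body.append(
            f'<text x="{_fmt(cx)}" y="{_fmt(cy)}" font-size="12" text-anchor="middle" '
            'data-role="notice">no mapped genes with a Cat1 label</text>'
        )
        return _svg_doc(2 * cx, 2 * cy, body)

    spans: dict[CategoryPath, tuple[float, float]] = {}
    angle = 0.0
    for i, (cat, n) in enumerate(sorted(counts[1].items())):
        span = 360.0 * n / total1
        spans[cat] = (angle, angle + span)
        angle += span
    # children subdivide the parent's span in proportion to the parent's own
    # count; genes whose path stops at the parent leave an explicit filler arc
    # so every ring still closes to 360 degrees
    fillers: dict[int, list[tuple[CategoryPath, float, float]]] = {2: [], 3: []}
    for level in (2, 3):
        by_parent: dict[CategoryPath, list[tuple[CategoryPath, int]]] = {}
        for cat, n in sorted(counts[level].items()):
            parent = cat.truncate(level - 1)
            by_parent.setdefault(parent, []).append((cat, n))  # type: ignore[arg-type]
        for parent, parent_n in sorted(counts[level - 1].items()):
            if parent not in spans:
                continue
            a0, a1 = spans[parent]
            angle = a0
            for cat, n in by_parent.get(parent, []):
                span = (a1 - a0) * n / parent_n
                spans[cat] = (angle, angle + span)
                angle += span
            if a1 - angle > 1e-12:
                fillers[level].append((parent, angle, a1))
    # spans unlabeled at ring 2 stay unlabeled at ring 3
    fillers[3].extend(fillers[2])

    cat1_order = [c for c, _ in sorted(counts[1].items())]
    color_of = {c: _RING_PALETTE[i % len(_RING_PALETTE)] for i, c in enumerate(cat1_order)}
    for level in (1, 2, 3):
        r0, r1 = radii[level - 1], radii[level]
        shade = (1.0, 0.75, 0.55)[level - 1]
        for cat in sorted(counts[level]):
            if cat not in spans:
                continue
            a0, a1 = spans[cat]
            base = color_of[CategoryPath(cat.cat1)]
            body.append(
                f'<path d="{_arc_path(cx, cy, r0, r1, a0, a1)}" fill="{base}" '
                f'fill-opacity="{_fmt(shade)}" stroke="#ffffff" stroke-width="1" '
                f'data-level="{level}" data-category="{_esc(cat.label)}" '
                f'data-count="{counts[level][cat]}" '
                f'data-start="{a0:.6f}" data-span="{a1 - a0:.6f}"/>'
            )
        for parent, a0, a1 in fillers.get(level, []):
            body.append(
                f'<path d="{_arc_path(cx, cy, r0, r1, a0, a1)}" fill="#f2f2f2" '
                f'stroke="#ffffff" stroke-width="1" data-level="{level}" '
                f'data-role="filler" data-parent="{_esc(parent.label)}" '
                f'data-start="{a0:.6f}" data-span="{a1 - a0:.6f}"/>'
            )
    body.append(
        f'<text x="{_fmt(cx)}" y="{_fmt(cy + 4)}" font-size="13" text-anchor="middle" '
        f'data-role="total">{total1}</text>'
    )
    return _svg_doc(2 * cx, 2 * cy, body)
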
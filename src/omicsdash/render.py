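"""Static rendering: per-panel SVG, whole-dashboard HTML, overlay export.

The renderer is deliberately a thin, deterministic projection of
:class:`~omicsdash.dashboard.PlotData`: identical inputs produce
byte-identical SVG/HTML, which makes rendered output directly testable.
Drill-down is realized as one SVG document per tree node plus hyperlinks
from the dashboard page.  Pathway-diagram *layout* is not computed here;
``overlay_export`` emits per-entity colors for any external diagram tool,
with an independent color scale per omics datatype (diverging and
centered at zero for relative data, sequential for absolute data).
"""

from __future__ import annotations

import hashlib
import json
import re

from .dashboard import (AxisAssignment, DashboardError, PlotData, PlotOptions,
                        panel_plots)
from .filters import FilterOutcome
from .hierarchy import DashboardTree, SubsystemNode
from .io import OmicsBundle
from .mapping import unmapped

# plot geometry (SVG user units)
PLOT_W, PLOT_H = 170, 150
MARGIN_L, MARGIN_R, MARGIN_T, MARGIN_B = 34, 34, 26, 12
GRID_COLS = 4


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _esc(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


def node_slug(uid: str) -> str:
    """Filesystem-safe, collision-free name for a node's SVG file."""
    safe = re.sub(r"[^A-Za-z0-9_-]+", "_", uid).strip("_")[:60]
    digest = hashlib.md5(uid.encode()).hexdigest()[:8]
    return f"{safe}-{digest}"


def _merge_ranges(plots: list[PlotData]) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for p in plots:
        for axis, (lo, hi) in p.y_range.items():
            if axis in out:
                out[axis] = (min(out[axis][0], lo), max(out[axis][1], hi))
            else:
                out[axis] = (lo, hi)
    return out


def _render_single_plot(plot: PlotData, x0: float, y0: float,
                        ranges: dict[str, tuple[float, float]],
                        axes: AxisAssignment) -> list[str]:
    parts = [f'<g transform="translate({_fmt(x0)},{_fmt(y0)})">']
    parts.append(
        f'<rect x="0" y="0" width="{PLOT_W}" height="{PLOT_H}" fill="white" '
        'stroke="#999999"/>')
    parts.append(
        f'<text x="{PLOT_W / 2}" y="16" text-anchor="middle" font-size="11">'
        f'{_esc(plot.abbreviation)}<title>{_esc(plot.title)}</title></text>')

    inner_w = PLOT_W - MARGIN_L - MARGIN_R
    inner_h = PLOT_H - MARGIN_T - MARGIN_B

    def ymap(axis: str, v: float) -> float:
        lo, hi = ranges[axis]
        frac = (v - lo) / (hi - lo) if hi > lo else 0.5
        return MARGIN_T + inner_h * (1.0 - frac)

    # axis tick labels (3 ticks per side in use)
    for axis in axes.axes_in_use():
        if axis not in ranges:
            continue
        side = axes.side_of_axis[axis]
        x = MARGIN_L - 4 if side == "left" else PLOT_W - MARGIN_R + 4
        anchor = "end" if side == "left" else "start"
        lo, hi = ranges[axis]
        for t in (lo, (lo + hi) / 2, hi):
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(ymap(axis, t) + 3)}" '
                f'text-anchor="{anchor}" font-size="7" fill="#555555">'
                f'{_fmt(t)}</text>')

    n = len(plot.columns)
    for i, col in enumerate(plot.columns):
        x = MARGIN_L + inner_w * (i + 1) / (n + 1)
        parts.append(
            f'<line x1="{_fmt(x)}" y1="{MARGIN_T}" x2="{_fmt(x)}" '
            f'y2="{MARGIN_T + inner_h}" stroke="{col.color}" '
            'stroke-width="1.5"/>')
        for (_, _), v in [(d, v) for d, v in col.dots]:
            parts.append(
                f'<circle cx="{_fmt(x)}" cy="{_fmt(ymap(col.axis, v))}" r="2" '
                f'fill="{col.color}"/>')
        my = ymap(col.axis, col.mean)
        parts.append(
            f'<circle cx="{_fmt(x)}" cy="{_fmt(my)}" r="4.5" '
            f'fill="{col.color}" stroke="#333333"/>')
        if plot.mean_text:
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(my - 7)}" text-anchor="middle" '
                f'font-size="8">{col.mean:.3g}</text>')

    if plot.excluded_count:
        names = ", ".join(plot.excluded_names)
        parts.append(
            f'<text x="{PLOT_W / 2}" y="{PLOT_H - 3}" text-anchor="middle" '
            f'font-size="7" fill="#aa0000">{plot.excluded_count} excluded'
            f'<title>excluded: {_esc(names)}</title></text>')
    parts.append("</g>")
    return parts


def render_panel(plots: list[PlotData], axes: AxisAssignment,
                 title: str = "") -> str:
    """Render one panel (a list of subsystem plots) to an SVG document.

    All plots share the panel's per-axis Y range (union of plot ranges);
    dual-axis panels annotate the first scale on the left side and the
    second on the right side of each plot.
    """
    if not plots:
        raise DashboardError("cannot render an empty panel")
    ranges = _merge_ranges(plots)
    ncols = min(GRID_COLS, len(plots))
    nrows = (len(plots) + ncols - 1) // ncols
    pad = 8
    top = 22 if title else 4
    width = ncols * (PLOT_W + pad) + pad
    height = nrows * (PLOT_H + pad) + pad + top
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="sans-serif">',
    ]
    if title:
        parts.append(
            f'<text x="{pad}" y="15" font-size="13" font-weight="bold">'
            f'{_esc(title)}</text>')
    for i, p in enumerate(plots):
        r, c = divmod(i, ncols)
        parts.extend(_render_single_plot(
            p, pad + c * (PLOT_W + pad), top + pad + r * (PLOT_H + pad),
            ranges, axes))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _legend_html(bundle: OmicsBundle, outcome: FilterOutcome) -> str:
    from .dashboard import column_color
    items = []
    for key in outcome.visible:
        items.append(
            f'<span class="legend-item"><span class="swatch" '
            f'style="background:{column_color(bundle, key)}"></span>'
            f'{_esc(bundle.legend_text(key))}</span>')
    return '<div class="legend">' + " ".join(items) + "</div>"


def render_dashboard(tree: DashboardTree, bundle: OmicsBundle,
                     outcome: FilterOutcome, axes: AxisAssignment,
                     pgdb=None, options: PlotOptions | None = None,
                     title: str = "Omics dashboard") -> dict[str, str]:
    """Render the whole dashboard to a file set.

    Returns ``{relative_path: content}`` with ``index.html`` plus one SVG
    per tree node (panel views for containers, per-entity graphs for base
    panels).  Top-level panels are inlined in the page in order, below a
    global legend; every plot links to its node's SVG for drill-down.  A
    final "Objects not present in any subsystem" section appears only
    when unmapped rows exist (requires ``pgdb`` to compute them).
    """
    files: dict[str, str] = {}
    html = [
        "<!DOCTYPE html>",
        f"<html><head><meta charset='utf-8'><title>{_esc(title)}</title>",
        "<style>body{font-family:sans-serif} .swatch{display:inline-block;"
        "width:12px;height:12px;margin-right:3px} .legend-item"
        "{margin-right:14px}</style></head><body>",
        f"<h1>{_esc(title)}</h1>",
        _legend_html(bundle, outcome),
    ]
    for node in tree.walk():
        plots = panel_plots(node, bundle, outcome, axes, options)
        if not plots:
            continue
        files[f"panels/{node_slug(node.uid)}.svg"] = render_panel(
            plots, axes, title=node.name)
    for panel in tree.panels:
        slug = node_slug(panel.uid)
        html.append(f'<section id="{slug}"><h2>{_esc(panel.name)}</h2>')
        svg = files.get(f"panels/{slug}.svg")
        if svg:
            # inline without the XML prolog
            html.append(svg.split("\n", 1)[1].rstrip())
        html.append("<ul>")
        for child in panel.children:
            cslug = node_slug(child.uid)
            html.append(
                f'<li><a href="panels/{cslug}.svg">{_esc(child.name)}</a></li>')
        html.append("</ul></section>")

    if pgdb is not None:
        leftover = unmapped(pgdb, bundle, tree)
        if leftover:
            plots = []
            for ds_idx, r in leftover:
                from .dashboard import plot_data
                catchall = SubsystemNode(
                    uid="__unmapped__", name="Objects not in any subsystem",
                    abbreviation="Unmapped", kind="custom", source_ids=())
                plots.append(plot_data(
                    catchall, bundle, outcome, axes, options,
                    entity_rows={ds_idx: [r]},
                    title=bundle.datasets[ds_idx].entity_name(r)))
            plots = [p for p in plots if p.columns]
            if plots:
                files["panels/unmapped.svg"] = render_panel(
                    plots, axes, title="Objects not present in any subsystem")
                html.append(
                    '<section id="unmapped"><h2>Show Objects Not Present in '
                    'any Subsystem</h2><a href="panels/unmapped.svg">'
                    f'{len(plots)} objects</a></section>')
    html.append("</body></html>")
    files["index.html"] = "\n".join(html) + "\n"
    return files


def write_render(files: dict[str, str], out_dir) -> None:
    import os
    for rel, content in files.items():
        path = os.path.join(out_dir, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(content)


# ---------------------------------------------------------------------------
# overlay export


def _lerp_color(c1: tuple, c2: tuple, t: float) -> str:
    rgb = tuple(round(a + (b - a) * t) for a, b in zip(c1, c2))
    return "#%02x%02x%02x" % rgb

_BLUE, _WHITE, _RED = (33, 102, 172), (247, 247, 247), (178, 24, 43)
_LIGHT, _DARK = (255, 245, 235), (127, 39, 4)


def diverging_palette(n: int) -> list[str]:
    """Blue-white-red ramp, centered color at the middle bin."""
    half = (n - 1) / 2
    out = []
    for i in range(n):
        if i < half:
            out.append(_lerp_color(_BLUE, _WHITE, i / half))
        elif i > half:
            out.append(_lerp_color(_WHITE, _RED, (i - half) / half))
        else:
            out.append("#%02x%02x%02x" % _WHITE)
    return out


def sequential_palette(n: int) -> list[str]:
    return [_lerp_color(_LIGHT, _DARK, i / (n - 1)) for i in range(n)]


def _bin_index(v: float, lo: float, hi: float, n_bins: int) -> int:
    if hi <= lo:
        return n_bins // 2
    i = int((v - lo) / (hi - lo) * n_bins)
    return min(max(i, 0), n_bins - 1)


def datatype_scale(bundle: OmicsBundle, datatype: str,
                   visible, n_bins: int = 9) -> dict:
    """Color scale over one datatype's global value range.

    Relative data use a diverging palette over a zero-centered symmetric
    range; absolute data a sequential palette over [min, max].
    """
    vals = []
    relative = False
    for key in visible:
        ds = bundle.datasets[key[0]]
        if ds.datatype != datatype:
            continue
        relative = ds.value_scale == "relative"
        for r in range(len(ds.rows)):
            v = ds.value(r, key[1])
            if v is not None:
                vals.append(v)
    if not vals:
        return {}
    if relative:
        m = max(abs(min(vals)), abs(max(vals))) or 1.0
        lo, hi = -m, m
        colors = diverging_palette(n_bins)
    else:
        lo, hi = min(vals), max(vals)
        colors = sequential_palette(n_bins)
    breakpoints = [lo + (hi - lo) * i / n_bins for i in range(n_bins + 1)]
    return {"datatype": datatype, "min": lo, "max": hi, "n_bins": n_bins,
            "breakpoints": breakpoints, "colors": colors,
            "palette": "diverging" if relative else "sequential"}


def overlay_export(node: SubsystemNode, bundle: OmicsBundle,
                   outcome: FilterOutcome, n_bins: int = 9) -> dict:
    """Per-entity overlay colors for a base pathway node.

    For every filtered member entity and visible column: the value, its
    bin and its color from the datatype's scale.  One independent scale
    per datatype present.  The result is JSON-serializable (see
    ``data/overlay.schema.json``).
    """
    if not node.is_base or node.kind != "pathway":
        raise DashboardError(
            f"overlay export needs a base pathway node, got {node.kind!r}")
    scales = {}
    for ds in bundle.datasets:
        if ds.datatype not in scales:
            s = datatype_scale(bundle, ds.datatype, outcome.visible, n_bins)
            if s:
                scales[ds.datatype] = s
    entities = []
    for ds_idx, rows in sorted(outcome.members_of(node.uid).items()):
        ds = bundle.datasets[ds_idx]
        scale = scales.get(ds.datatype)
        for r in rows:
            values = []
            for key in outcome.visible:
                if key[0] != ds_idx:
                    continue
                v = ds.value(r, key[1])
                if v is None or scale is None:
                    values.append({"column": bundle.labels[key], "value": None,
                                   "color": None})
                else:
                    b = _bin_index(v, scale["min"], scale["max"], n_bins)
                    values.append({"column": bundle.labels[key], "value": v,
                                   "bin": b, "color": scale["colors"][b]})
            entities.append({"entity": ds.entity_name(r),
                             "datatype": ds.datatype, "values": values})
    return {"pathway_id": node.source_ids[0], "node": node.uid,
            "entities": entities, "scales": scales}


def overlay_json(node, bundle, outcome, n_bins: int = 9) -> str:
    return json.dumps(overlay_export(node, bundle, outcome, n_bins),
                      indent=2, sort_keys=True) + "\n"
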
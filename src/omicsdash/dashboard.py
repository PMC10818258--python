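"""Plot-ready aggregation, axis assignment, column styling, search, tables.

Each subsystem plot draws one vertical line per visible data column; small
dots are individual entity values, the large circle on each line is the
arithmetic mean over the (filtered, non-missing) member values.  With two
component datasets each owns a Y-axis; with three, exactly two must share
one — and if their value scales differ (log fold-change vs absolute
quantities), the two with the same scale are forced together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .filters import FilterOutcome
from .hierarchy import DashboardTree, SubsystemNode
from .io import OmicsBundle, OmicsIOError

DisplayKey = tuple[int, int]
RowKey = tuple[int, int]

#: deterministic 12-color cycle for data columns
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


class DashboardError(Exception):
    pass


class AxisConstraintError(DashboardError):
    """Raised when a user axis pairing violates the sharing rules."""


# ---------------------------------------------------------------------------
# axis assignment


@dataclass(frozen=True)
class AxisAssignment:
    """Which Y-axis each dataset uses, and which side each axis sits on.

    ``axis_of_dataset[i]`` is "A" or "B"; ``side_of_axis`` maps axis to
    "left"/"right".  All datasets on one axis share a value scale.
    """

    axis_of_dataset: tuple[str, ...]
    side_of_axis: dict[str, str]
    label_of_axis: dict[str, str]
    grid_color_of_axis: dict[str, str] = field(
        default_factory=lambda: {"A": "#cccccc", "B": "#e0cfe0"})

    def axes_in_use(self) -> list[str]:
        seen = []
        for a in self.axis_of_dataset:
            if a not in seen:
                seen.append(a)
        return seen

    def datasets_on(self, axis: str) -> list[int]:
        return [i for i, a in enumerate(self.axis_of_dataset) if a == axis]


def _scale_of(ds) -> str:
    return ds.value_scale


def _validate_grouping(bundle: OmicsBundle, axes: tuple[str, ...]) -> None:
    n = len(bundle.datasets)
    if len(axes) != n:
        raise AxisConstraintError("assignment length mismatch")
    used = set(axes)
    if not used <= {"A", "B"}:
        raise AxisConstraintError("axes are named 'A' and 'B'")
    if n == 3 and len(used) != 2:
        raise AxisConstraintError(
            "with three component datasets exactly two must share a Y-axis")
    if n == 2 and len(used) != 2:
        raise AxisConstraintError(
            "with two component datasets each gets its own Y-axis")
    for axis in used:
        scales = {_scale_of(bundle.datasets[i]) for i, a in enumerate(axes)
                  if a == axis}
        if len(scales) > 1:
            raise AxisConstraintError(
                "datasets sharing a Y-axis must have the same value scale"
                " (relative vs absolute); the two with the same type of data"
                " must share")


def assign_axes(bundle: OmicsBundle,
                share_pair: tuple[int, int] | None = None,
                sides: dict[str, str] | None = None) -> AxisAssignment:
    """Compute a constraint-satisfying axis assignment.

    ``share_pair`` names the two dataset indices to put on one axis (only
    meaningful with three datasets); invalid pairings are rejected.  When
    unconstrained the first valid pairing in index order is chosen.
    ``sides`` maps axis name to "left"/"right" (default A-left, B-right).
    """
    n = len(bundle.datasets)
    if n == 1:
        axes: tuple[str, ...] = ("A",)
    elif n == 2:
        axes = ("A", "B")
    elif n == 3:
        if share_pair is not None:
            i, j = sorted(share_pair)
            if not (0 <= i < j < 3):
                raise AxisConstraintError(f"bad dataset pair {share_pair}")
            axes = tuple("A" if k in (i, j) else "B" for k in range(3))
            _validate_grouping(bundle, axes)
        else:
            for i, j in ((0, 1), (0, 2), (1, 2)):
                axes = tuple("A" if k in (i, j) else "B" for k in range(3))
                try:
                    _validate_grouping(bundle, axes)
                    break
                except AxisConstraintError:
                    continue
            else:  # pragma: no cover - two scales always admit a pairing
                raise AxisConstraintError("no valid axis assignment exists")
    else:
        raise DashboardError("bundles hold at most 3 datasets")
    if n == 2:
        _validate_grouping(bundle, axes)

    side_of_axis = {"A": "left", "B": "right"}
    if sides:
        if sorted(sides) != sorted(set(axes)) or \
                sorted(sides.values()) != sorted(
                    ["left", "right"][: len(set(axes))]):
            raise AxisConstraintError(f"bad side assignment {sides}")
        side_of_axis.update(sides)

    labels = {}
    for axis in set(axes):
        ds_on = [bundle.datasets[i] for i, a in enumerate(axes) if a == axis]
        dts = "/".join(dict.fromkeys(d.datatype for d in ds_on))
        scale = ds_on[0].value_scale
        if scale == "relative" and ds_on[0].log_transformed:
            scale = "log ratio"
        labels[axis] = f"{dts} ({scale})"
    return AxisAssignment(axis_of_dataset=axes, side_of_axis=side_of_axis,
                          label_of_axis=labels)


# ---------------------------------------------------------------------------
# plot aggregation


@dataclass
class PlotColumn:
    key: DisplayKey
    label: str
    legend: str
    color: str
    axis: str
    dots: list[tuple[RowKey, float]]
    mean: float
    n_log_omitted: int = 0


@dataclass
class PlotData:
    """Everything needed to draw one subsystem plot."""

    node_uid: str
    title: str
    abbreviation: str
    columns: list[PlotColumn]
    mean_text: bool
    y_range: dict[str, tuple[float, float]]
    excluded_count: int = 0
    excluded_names: list[str] = field(default_factory=list)


@dataclass
class PlotOptions:
    log_scale: bool = False      # log10 display transform for absolute data
    y_override: dict[str, tuple[float, float]] | None = None


def column_color(bundle: OmicsBundle, key: DisplayKey) -> str:
    if key in bundle.colors:
        return bundle.colors[key]
    return PALETTE[bundle.display_order.index(key) % len(PALETTE)]


def _pad_range(lo: float, hi: float) -> tuple[float, float]:
    if lo == hi:
        lo, hi = lo - 1.0, hi + 1.0
    pad = 0.05 * (hi - lo)
    return (lo - pad, hi + pad)


def plot_data(node: SubsystemNode, bundle: OmicsBundle,
              outcome: FilterOutcome, axes: AxisAssignment,
              options: PlotOptions | None = None,
              entity_rows: dict[int, list[int]] | None = None,
              title: str | None = None) -> PlotData:
    """Aggregate one subsystem into plot form.

    One line per visible display column with at least one member value
    (empty columns are omitted); the mean is arithmetic over non-missing
    values.  The mean-as-text flag is set only when exactly one data
    column is visible.  ``options.log_scale`` applies a log10 display
    transform and is refused for log-ratio data; non-positive values are
    omitted from log plots with a count.  ``entity_rows`` restricts the
    member rows (used for per-entity base-panel plots).
    """
    options = options or PlotOptions()
    members = entity_rows if entity_rows is not None \
        else outcome.members_of(node.uid)
    columns: list[PlotColumn] = []
    for key in outcome.visible:
        ds_idx, col_idx = key
        ds = bundle.datasets[ds_idx]
        if options.log_scale and ds.is_log_relative:
            raise DashboardError(
                "log-scale display is not available for log fold-change data")
        dots: list[tuple[RowKey, float]] = []
        n_omitted = 0
        for r in members.get(ds_idx, []):
            v = ds.value(r, col_idx)
            if v is None:
                continue
            if options.log_scale:
                if v <= 0:
                    n_omitted += 1
                    continue
                v = math.log10(v)
            dots.append(((ds_idx, r), v))
        if not dots:
            continue
        mean = sum(v for _, v in dots) / len(dots)
        columns.append(PlotColumn(
            key=key, label=bundle.labels[key], legend=bundle.legend_text(key),
            color=column_color(bundle, key),
            axis=axes.axis_of_dataset[ds_idx], dots=dots, mean=mean,
            n_log_omitted=n_omitted))

    y_range: dict[str, tuple[float, float]] = {}
    for axis in axes.axes_in_use():
        vals = [v for c in columns if c.axis == axis for _, v in c.dots]
        vals += [c.mean for c in columns if c.axis == axis]
        if vals:
            y_range[axis] = _pad_range(min(vals), max(vals))
    if options.y_override:
        y_range.update(options.y_override)

    excluded = outcome.node_excluded.get(node.uid, []) \
        if entity_rows is None else []
    names = [bundle.datasets[d].entity_name(r) for (d, r), _ in excluded]
    return PlotData(node_uid=node.uid, title=title or node.name,
                    abbreviation=node.abbreviation, columns=columns,
                    mean_text=len(outcome.visible) == 1,
                    y_range=y_range, excluded_count=len(excluded),
                    excluded_names=sorted(set(names)))


def panel_plots(node: SubsystemNode, bundle: OmicsBundle,
                outcome: FilterOutcome, axes: AxisAssignment,
                options: PlotOptions | None = None) -> list[PlotData]:
    """Plots of one panel: child subsystems, or per-entity graphs for a
    base panel."""
    if not node.is_base:
        return [plot_data(c, bundle, outcome, axes, options)
                for c in node.children]
    plots = []
    for ds_idx, rows in sorted(outcome.members_of(node.uid).items()):
        for r in rows:
            pd_ = plot_data(node, bundle, outcome, axes, options,
                            entity_rows={ds_idx: [r]},
                            title=bundle.datasets[ds_idx].entity_name(r))
            plots.append(pd_)
    return plots


# ---------------------------------------------------------------------------
# column order and style


def reorder_columns(bundle: OmicsBundle,
                    new_order: list[DisplayKey]) -> OmicsBundle:
    """Set the display order; must be a permutation of the data columns."""
    if sorted(new_order) != sorted(bundle.display_order) or \
            len(new_order) != len(bundle.display_order):
        raise DashboardError("new order is not a permutation of display columns")
    return OmicsBundle(datasets=bundle.datasets, display_order=list(new_order),
                       labels=dict(bundle.labels), colors=dict(bundle.colors))


def restyle_column(bundle: OmicsBundle, key: DisplayKey,
                   label: str | None = None,
                   color: str | None = None) -> OmicsBundle:
    if key not in bundle.display_order:
        raise DashboardError(f"no such display column {key}")
    labels, colors = dict(bundle.labels), dict(bundle.colors)
    if label is not None:
        labels[key] = label
    if color is not None:
        colors[key] = color
    return OmicsBundle(datasets=bundle.datasets,
                       display_order=list(bundle.display_order),
                       labels=labels, colors=colors)


def interleave_by_condition(bundle: OmicsBundle) -> list[DisplayKey]:
    """Column order grouping the k-th column of every dataset together
    (all data for condition 1, then condition 2, ...)."""
    per_ds: dict[int, list[DisplayKey]] = {}
    for key in bundle.display_order:
        per_ds.setdefault(key[0], []).append(key)
    out: list[DisplayKey] = []
    k = 0
    while any(k < len(v) for v in per_ds.values()):
        for ds_idx in sorted(per_ds):
            if k < len(per_ds[ds_idx]):
                out.append(per_ds[ds_idx][k])
        k += 1
    return out


# ---------------------------------------------------------------------------
# search


def autocomplete(bundle: OmicsBundle, prefix: str, limit: int = 20) -> list[str]:
    """Case-folded prefix completion over dataset entity names."""
    p = prefix.casefold()
    names = sorted({name for ds in bundle.datasets for name, _ in ds.rows})
    return [n for n in names if n.casefold().startswith(p)][:limit]


def search(tree: DashboardTree, outcome: FilterOutcome, bundle: OmicsBundle,
           query: str) -> list[str]:
    """Base-node uids whose filtered members include an entity whose name
    starts with the query (case-folded)."""
    q = query.casefold()
    hits = []
    for node in tree.base_nodes():
        for ds_idx, rows in outcome.members_of(node.uid).items():
            ds = bundle.datasets[ds_idx]
            if any(ds.entity_name(r).casefold().startswith(q) for r in rows):
                hits.append(node.uid)
                break
    return hits


# ---------------------------------------------------------------------------
# table export


def export_table(node: SubsystemNode, bundle: OmicsBundle,
                 outcome: FilterOutcome,
                 sort_by: str | None = None,
                 ascending: bool = True) -> pd.DataFrame:
    """All data for one subsystem as a table.

    One row per (filtered) member entity across all datatypes; one column
    per visible data column, labelled with its legend text.  Sorting is
    stable with missing values last.
    """
    records = []
    for ds_idx, rows in sorted(outcome.members_of(node.uid).items()):
        ds = bundle.datasets[ds_idx]
        for r in rows:
            rec = {"entity": ds.entity_name(r), "datatype": ds.datatype}
            for key in outcome.visible:
                col = bundle.legend_text(key)
                rec[col] = bundle.value(key, r) if key[0] == ds_idx else None
            records.append(rec)
    cols = ["entity", "datatype"] + [bundle.legend_text(k)
                                     for k in outcome.visible]
    df = pd.DataFrame.from_records(records, columns=cols)
    if sort_by is not None:
        if sort_by not in df.columns:
            raise DashboardError(f"no such column {sort_by!r}")
        df = df.sort_values(sort_by, ascending=ascending, kind="stable",
                            na_position="last").reset_index(drop=True)
    return df
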
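"""Data filtering: value, significance and common-metabolite filters.

Filtering is per entity: a row that meets the criteria in *any visible
data column* is included, and once included, *all* its data columns are
displayed — averages and distributions are only comparable across
timepoints when the same entity set underlies every column.  When several
filters are configured a row must pass all of them (conjunction).

The common-metabolite filter is node-contextual: hub compounds (by
default those participating in ten or more pathways) can be excluded from
the display, but remain visible in any pathway for which a curator has
designated them a primary input or output — and in every system and
subsystem containing such a pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import mapping
from .hierarchy import DashboardTree, SubsystemNode
from .io import OmicsBundle
from .pgdb import PGDB

DisplayKey = tuple[int, int]
RowKey = tuple[int, int]


class FilterError(Exception):
    pass


@dataclass(frozen=True)
class ValueFilter:
    """Keep rows with a data value above (min) / below (max) a threshold,
    optionally on the absolute value; comparisons are inclusive."""

    threshold: float
    direction: str = "min"  # "min" | "max"
    use_absolute_value: bool = False

    def __post_init__(self):
        if self.direction not in ("min", "max"):
            raise FilterError(f"bad direction {self.direction!r}")

    def passes(self, v: float) -> bool:
        x = abs(v) if self.use_absolute_value else v
        return x >= self.threshold if self.direction == "min" else x <= self.threshold


@dataclass(frozen=True)
class SignificanceFilter:
    """Keep rows whose significance value for some visible data column
    meets the threshold (for p-values, a maximum).

    ``column_map`` maps a data display column to its significance column
    within the same dataset; when ``None`` it is derived from the
    datasets' declared ``significance_for`` links.  Data columns without a
    mapped significance column are not considered.
    """

    threshold: float
    direction: str = "max"
    column_map: tuple[tuple[DisplayKey, int], ...] | None = None

    def __post_init__(self):
        if self.direction not in ("min", "max"):
            raise FilterError(f"bad direction {self.direction!r}")

    def resolved_map(self, bundle: OmicsBundle) -> dict[DisplayKey, int]:
        if self.column_map is not None:
            out = dict(self.column_map)
            for (ds_idx, _), sig_col in out.items():
                sig_cols = {c.index for c in
                            bundle.datasets[ds_idx].significance_columns}
                if sig_col not in sig_cols:
                    raise FilterError(
                        f"column {sig_col} of dataset {ds_idx} is not a"
                        " significance column")
            return out
        out = {}
        for ds_idx, ds in enumerate(bundle.datasets):
            for data_col, sig_col in ds.significance_map().items():
                out[(ds_idx, data_col)] = sig_col
        return out

    def passes(self, s: float) -> bool:
        return s >= self.threshold if self.direction == "min" else s <= self.threshold


@dataclass(frozen=True)
class CommonMetaboliteFilter:
    """Exclude user-selected hub metabolites outside their primary-io
    pathways; the candidate checklist is advisory (threshold ≥ is
    inclusive: "ten or more")."""

    pathway_count_threshold: int = 10
    excluded_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.pathway_count_threshold < 1:
            raise FilterError("pathway_count_threshold must be >= 1")


@dataclass
class FilterConfig:
    value_filter: ValueFilter | None = None
    significance_filter: SignificanceFilter | None = None
    common_metabolite_filter: CommonMetaboliteFilter | None = None
    visible_columns: frozenset[DisplayKey] | None = None  # None = all visible

    def visible(self, bundle: OmicsBundle) -> list[DisplayKey]:
        order = bundle.display_order
        if self.visible_columns is None:
            return list(order)
        return [k for k in order if k in self.visible_columns]


@dataclass
class FilterOutcome:
    """Filtered membership per node plus exclusion bookkeeping."""

    included_rows: set[RowKey]
    node_members: dict[str, dict[int, list[int]]]
    node_excluded: dict[str, list[tuple[RowKey, str]]]
    candidates: list[tuple[str, int]] = field(default_factory=list)
    visible: list[DisplayKey] = field(default_factory=list)

    def excluded_count(self, node_uid: str) -> int:
        return len(self.node_excluded.get(node_uid, []))

    def members_of(self, node_uid: str) -> dict[int, list[int]]:
        return self.node_members.get(node_uid, {})

    def member_row_keys(self, node_uid: str) -> list[RowKey]:
        return [(d, r) for d, rows in
                sorted(self.members_of(node_uid).items()) for r in rows]


# ---------------------------------------------------------------------------
# row-level predicates


def value_pass(bundle: OmicsBundle, row: RowKey, vf: ValueFilter,
               visible: list[DisplayKey]) -> bool:
    """True iff some visible data column of the row's dataset passes."""
    ds_idx, row_idx = row
    for key in visible:
        if key[0] != ds_idx:
            continue
        v = bundle.value(key, row_idx)
        if v is not None and vf.passes(v):
            return True
    return False


def significance_pass(bundle: OmicsBundle, row: RowKey, sf: SignificanceFilter,
                      visible: list[DisplayKey],
                      column_map: dict[DisplayKey, int] | None = None) -> bool:
    """True iff some visible, significance-mapped data column passes.

    A missing significance value for a mapped column cannot pass.
    """
    if column_map is None:
        column_map = sf.resolved_map(bundle)
    ds_idx, row_idx = row
    for key in visible:
        if key[0] != ds_idx or key not in column_map:
            continue
        s = bundle.datasets[ds_idx].value(row_idx, column_map[key])
        if s is not None and sf.passes(s):
            return True
    return False


# ---------------------------------------------------------------------------
# common-metabolite machinery


def common_candidates(pgdb: PGDB, bundle: OmicsBundle, resolution,
                      threshold: int = 10) -> list[tuple[str, int]]:
    """Hub-metabolite checklist: resolved metabolites in >= threshold
    pathways, sorted by pathway count descending (ties alphabetical)."""
    if not bundle.has_metabolomics:
        raise FilterError(
            "the common-metabolite filter is available only for datasets with"
            " a metabolomics component")
    counts: dict[str, int] = {}
    for ds_idx, ds in enumerate(bundle.datasets):
        if ds.datatype != "metabolomics":
            continue
        for ent in resolution[ds_idx]:
            for cid in ent.matched_ids:
                if cid not in counts:
                    counts[cid] = pgdb.pathway_count(cid)
    hits = [(cid, n) for cid, n in counts.items() if n >= threshold]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def _excluded_compounds_of_row(ent: mapping.ResolvedEntity,
                               excluded_ids: frozenset[str]) -> set[str]:
    return set(ent.matched_ids) & excluded_ids


def _primary_io_exempt(pgdb: PGDB, node: SubsystemNode,
                       excluded_cids: set[str]) -> bool:
    """Does the node contain a pathway whose primary inputs/outputs cover
    one of the excluded compounds (closure-expanded)?"""
    for cid in excluded_cids:
        closure = pgdb.compound_closure(cid)
        for pwy_id in node.pathway_ids:
            if closure & pgdb.pathways[pwy_id].primary_ids:
                return True
    return False


# ---------------------------------------------------------------------------
# full application


def apply_filters(pgdb: PGDB, bundle: OmicsBundle, tree: DashboardTree,
                  config: FilterConfig) -> FilterOutcome:
    """Apply all configured filters over the whole tree.

    The value and significance filters act globally (conjunction); the
    common-metabolite exclusion acts per node, honouring the primary
    input/output exemption for the qualifying pathway and all its
    ancestors.  Per-node exclusion lists record row and reason; for base
    nodes the exclusion count equals the member-count difference.
    """
    resolution = getattr(tree, "resolution", None)
    if resolution is None:
        resolution = mapping.resolve_bundle(pgdb, bundle)
    visible = config.visible(bundle)

    vf, sf, cf = (config.value_filter, config.significance_filter,
                  config.common_metabolite_filter)
    sig_map = sf.resolved_map(bundle) if sf else None

    included: set[RowKey] = set()
    for row in bundle.all_row_keys():
        ok = True
        if vf is not None:
            ok = value_pass(bundle, row, vf, visible)
        if ok and sf is not None:
            ok = significance_pass(bundle, row, sf, visible, sig_map)
        if ok:
            included.add(row)

    candidates: list[tuple[str, int]] = []
    row_excluded_cids: dict[RowKey, set[str]] = {}
    if cf is not None:
        candidates = common_candidates(pgdb, bundle, resolution,
                                       cf.pathway_count_threshold)
        if cf.excluded_ids:
            for ds_idx, ents in resolution.items():
                if bundle.datasets[ds_idx].datatype != "metabolomics":
                    continue
                for ent in ents:
                    cids = _excluded_compounds_of_row(ent, cf.excluded_ids)
                    if cids:
                        row_excluded_cids[ent.row_key] = cids

    node_members: dict[str, dict[int, list[int]]] = {}
    node_excluded: dict[str, list[tuple[RowKey, str]]] = {}
    for node in tree.walk():
        kept: dict[int, list[int]] = {}
        dropped: list[tuple[RowKey, str]] = []
        for ds_idx, rows in node.members.items():
            keep_rows = []
            for r in rows:
                key = (ds_idx, r)
                if key not in included:
                    dropped.append((key, "failed value/significance filter"))
                    continue
                cids = row_excluded_cids.get(key)
                if cids and not _primary_io_exempt(pgdb, node, cids):
                    dropped.append((key, "common metabolite excluded"))
                    continue
                keep_rows.append(r)
            if keep_rows:
                kept[ds_idx] = keep_rows
        node_members[node.uid] = kept
        if dropped:
            node_excluded[node.uid] = dropped

    return FilterOutcome(included_rows=included, node_members=node_members,
                         node_excluded=node_excluded, candidates=candidates,
                         visible=visible)


def no_filters() -> FilterConfig:
    """A pass-through configuration (all rows included, all columns visible)."""
    return FilterConfig()
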
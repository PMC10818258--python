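"""Construction of the dashboard's system/subsystem tree.

The four metabolic panels (Biosynthesis, Degradation, Energy Metabolism,
Other Pathways) derive from the pathway-class taxonomy: within each panel
a curated list of classes appears explicitly, classes below a configured
depth are flattened, uncurated siblings merge into an "Other" bucket, and
the lowest level holds individual pathways (the *base* subsystems).
Non-metabolic panels (Central Dogma, Response to Stimulus, ...) derive
from curated GO-term groups, plus subsystems computed from transporter /
regulator activity tags; they are built only when the bundle carries gene
data (transcriptomics, proteomics or flux), since metabolomics data
cannot be displayed on them.

Every panel and plot is pruned when no dataset row maps to it, so the
rendered tree is both organism- and dataset-dependent.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from . import mapping
from .io import OmicsBundle
from .pgdb import METABOLIC_ROOT_IDS, PGDB

NON_METABOLIC_PANELS = (
    "Central-Dogma", "Response-to-Stimulus", "Cellular-Processes",
    "Virulence-Related", "Cell-Exterior",
)


class HierarchyError(Exception):
    pass


def abbreviate(name: str, overrides: dict[str, str] | None = None) -> str:
    """Short plot label: configured override, else first letters of words."""
    if overrides and name in overrides:
        return overrides[name]
    words = name.replace("-", " ").replace("_", " ").split()
    if len(words) <= 1:
        return name[:12]
    return "".join(w[0].upper() for w in words)


@dataclass
class DashboardConfig:
    """Curation of the tree: which classes/GO groups appear, flatten depth.

    ``curated_classes`` maps a parent class id to the ordered child class
    ids shown explicitly; children of a listed parent that are absent from
    its list collapse into an "Other" bucket.  Parents without an entry
    show all children (alphabetical).  ``go_panels`` maps panel name ->
    group name -> list of GO term ids.  ``activity_panels`` maps panel
    name -> list of activity tags.
    """

    flatten_depth: int = 3
    curated_classes: dict[str, list[str]] = field(default_factory=dict)
    go_panels: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    activity_panels: dict[str, list[str]] = field(default_factory=dict)
    abbreviations: dict[str, str] = field(default_factory=dict)
    exclude_nodes: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "DashboardConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in raw.items() if v is not None})

    @classmethod
    def default(cls) -> "DashboardConfig":
        ref = importlib.resources.files("omicsdash") / "data" / "default_config.yaml"
        with ref.open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in raw.items() if v is not None})


@dataclass
class SubsystemNode:
    """One dashboard panel or plot.

    ``uid`` is the slash-joined path from the panel root, so nodes are
    unique even when a pathway sits under two classes.  ``members`` maps
    dataset index to the sorted row indices mapped here (pre-filtering).
    """

    uid: str
    name: str
    abbreviation: str
    kind: str  # pathway-class | pathway | go-group | go-term | activity | custom | other-bucket
    source_ids: tuple[str, ...]
    children: list["SubsystemNode"] = field(default_factory=list)
    parent_uid: str | None = None
    pathway_ids: frozenset[str] = frozenset()
    go_ids: frozenset[str] = frozenset()
    activity_tag: str | None = None
    entity_ids: frozenset[str] = frozenset()
    members: dict[int, list[int]] = field(default_factory=dict)

    @property
    def is_base(self) -> bool:
        return not self.children

    def member_row_keys(self) -> set[tuple[int, int]]:
        return {(d, r) for d, rows in self.members.items() for r in rows}

    def n_members(self) -> int:
        return sum(len(r) for r in self.members.values())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class DashboardTree:
    """Ordered top-level panels plus an index of every node by uid."""

    panels: list[SubsystemNode]
    nodes: dict[str, SubsystemNode] = field(default_factory=dict)

    def __post_init__(self):
        self.reindex()

    def reindex(self) -> None:
        self.nodes = {}
        for p in self.panels:
            for n in p.walk():
                self.nodes[n.uid] = n

    def walk(self):
        for p in self.panels:
            yield from p.walk()

    def base_nodes(self) -> list[SubsystemNode]:
        return [n for n in self.walk() if n.is_base]

    def get(self, uid: str) -> SubsystemNode:
        try:
            return self.nodes[uid]
        except KeyError:
            raise HierarchyError(f"unknown subsystem node {uid!r}") from None


# ---------------------------------------------------------------------------
# construction


def _pathway_leaf(pgdb: PGDB, pwy_id: str, parent_uid: str,
                  config: DashboardConfig) -> SubsystemNode:
    pwy = pgdb.pathways[pwy_id]
    return SubsystemNode(
        uid=f"{parent_uid}/{pwy_id}", name=pwy.name,
        abbreviation=abbreviate(pwy.name, config.abbreviations),
        kind="pathway", source_ids=(pwy_id,), parent_uid=parent_uid,
        pathway_ids=frozenset({pwy_id}))


def _build_class_node(pgdb: PGDB, class_id: str, parent_uid: str | None,
                      config: DashboardConfig, depth: int) -> SubsystemNode:
    pc = pgdb.pathway_classes[class_id]
    uid = f"{parent_uid}/{class_id}" if parent_uid else class_id
    node = SubsystemNode(
        uid=uid, name=pc.name,
        abbreviation=abbreviate(pc.name, config.abbreviations),
        kind="pathway-class", source_ids=(class_id,), parent_uid=parent_uid,
        pathway_ids=pgdb.pathways_under_class(class_id))

    if depth >= config.flatten_depth:
        # flatten: everything below becomes direct pathway leaves
        for pwy_id in sorted(node.pathway_ids):
            node.children.append(_pathway_leaf(pgdb, pwy_id, uid, config))
        return node

    children = pgdb.class_children(class_id)
    if class_id in config.curated_classes:
        curated = [c for c in config.curated_classes[class_id] if c in children]
        unknown = set(config.curated_classes[class_id]) - set(children)
        if unknown - set(pgdb.pathway_classes):
            raise HierarchyError(
                f"config lists unknown pathway classes {sorted(unknown)}"
                f" under {class_id!r}")
        uncurated = sorted(set(children) - set(curated))
    else:
        curated, uncurated = children, []

    covered: set[str] = set()
    for child_id in curated:
        child = _build_class_node(pgdb, child_id, uid, config, depth + 1)
        covered |= child.pathway_ids
        node.children.append(child)

    leftover = sorted(node.pathway_ids - covered)
    if leftover:
        if node.children:
            bucket = SubsystemNode(
                uid=f"{uid}/other", name=f"Other {pc.name}",
                abbreviation=abbreviate(f"Other {pc.name}", config.abbreviations),
                kind="other-bucket", source_ids=tuple(uncurated),
                parent_uid=uid, pathway_ids=frozenset(leftover))
            for pwy_id in leftover:
                bucket.children.append(_pathway_leaf(pgdb, pwy_id, bucket.uid, config))
            node.children.append(bucket)
        else:
            for pwy_id in leftover:
                node.children.append(_pathway_leaf(pgdb, pwy_id, uid, config))
    return node


def _build_go_panel(pgdb: PGDB, panel_name: str,
                    groups: dict[str, list[str]],
                    activity_tags: list[str],
                    config: DashboardConfig) -> SubsystemNode:
    panel = SubsystemNode(
        uid=panel_name, name=panel_name.replace("-", " "),
        abbreviation=abbreviate(panel_name.replace("-", " "), config.abbreviations),
        kind="go-group", source_ids=())
    all_terms: set[str] = set()
    for group_name in groups:
        term_ids = groups[group_name]
        unknown = set(term_ids) - set(pgdb.go_terms)
        if unknown:
            raise HierarchyError(
                f"config lists unknown GO terms {sorted(unknown)} in {group_name!r}")
        closure: set[str] = set()
        for t in term_ids:
            closure |= pgdb.go_descendants[t]
        group = SubsystemNode(
            uid=f"{panel_name}/{group_name}", name=group_name.replace("-", " "),
            abbreviation=abbreviate(group_name.replace("-", " "),
                                    config.abbreviations),
            kind="go-group", source_ids=tuple(term_ids), parent_uid=panel_name,
            go_ids=frozenset(closure))
        for t in term_ids:
            term = pgdb.go_terms[t]
            group.children.append(SubsystemNode(
                uid=f"{group.uid}/{t}", name=term.name,
                abbreviation=abbreviate(term.name, config.abbreviations),
                kind="go-term", source_ids=(t,), parent_uid=group.uid,
                go_ids=pgdb.go_descendants[t]))
        all_terms |= closure
        panel.children.append(group)
    for tag in activity_tags:
        panel.children.append(SubsystemNode(
            uid=f"{panel_name}/{tag}", name=tag.capitalize() + "s",
            abbreviation=abbreviate(tag.capitalize() + "s", config.abbreviations),
            kind="activity", source_ids=(tag,), parent_uid=panel_name,
            activity_tag=tag))
    panel.go_ids = frozenset(all_terms)
    return panel


def _compute_members(pgdb: PGDB, node: SubsystemNode, bundle: OmicsBundle,
                     resolution) -> None:
    """Node membership = own matching rule ∪ children's members.

    The union keeps containers whose children follow different rules
    (activity plots inside a GO panel, mixed custom panels) consistent
    with the tree-containment monotonicity invariant.
    """
    merged: dict[int, set[int]] = {}
    for child in node.children:
        _compute_members(pgdb, child, bundle, resolution)
        for d, rows in child.members.items():
            merged.setdefault(d, set()).update(rows)
    for d, rows in mapping.members(pgdb, node, bundle, resolution).items():
        merged.setdefault(d, set()).update(rows)
    node.members = {d: sorted(rows) for d, rows in sorted(merged.items())}


def _prune(node: SubsystemNode) -> bool:
    """Drop zero-member descendants; return True if the node survives."""
    node.children = [c for c in node.children if _prune(c)]
    return node.n_members() > 0


def build_tree(pgdb: PGDB, bundle: OmicsBundle,
               config: DashboardConfig | None = None,
               resolution=None) -> DashboardTree:
    """Build the pruned dashboard tree for a PGDB and a resolved bundle."""
    config = config or DashboardConfig.default()
    if resolution is None:
        resolution = mapping.resolve_bundle(pgdb, bundle)

    panels: list[SubsystemNode] = []
    for root in METABOLIC_ROOT_IDS:
        if root in pgdb.pathway_classes:
            panels.append(_build_class_node(pgdb, root, None, config, depth=0))

    if bundle.has_gene_data:
        panel_names = [p for p in NON_METABOLIC_PANELS
                       if p in config.go_panels or p in config.activity_panels]
        # config may define additional panels beyond the standard five
        panel_names += [p for p in sorted(set(config.go_panels)
                                          | set(config.activity_panels))
                        if p not in panel_names]
        for name in panel_names:
            panels.append(_build_go_panel(
                pgdb, name, config.go_panels.get(name, {}),
                config.activity_panels.get(name, []), config))

    for p in panels:
        _compute_members(pgdb, p, bundle, resolution)

    if config.exclude_nodes:
        excluded = set(config.exclude_nodes)

        def drop(node):
            node.children = [c for c in node.children
                             if not (set(c.source_ids) & excluded)]
            for c in node.children:
                drop(c)

        for p in panels:
            drop(p)

    panels = [p for p in panels if _prune(p)]
    tree = DashboardTree(panels=panels)
    tree.resolution = resolution
    return tree


def add_custom_panel(tree: DashboardTree, pgdb: PGDB, bundle: OmicsBundle,
                     name: str, entity_ids: list[str],
                     config: DashboardConfig | None = None) -> DashboardTree:
    """Append a top-level panel built from a custom id list.

    Each listed id becomes one plot: pathway ids and pathway-class ids use
    pathway membership rules, GO terms use annotation rollup, gene and
    compound ids become explicit-entity plots.  Empty plots are pruned.
    """
    config = config or DashboardConfig()
    if not entity_ids:
        raise HierarchyError("custom panel needs a non-empty id list")
    resolution = getattr(tree, "resolution", None) or mapping.resolve_bundle(pgdb, bundle)
    uid = f"custom:{name}"
    panel = SubsystemNode(uid=uid, name=name,
                          abbreviation=abbreviate(name, config.abbreviations),
                          kind="custom", source_ids=tuple(entity_ids))
    for eid in entity_ids:
        if eid in pgdb.pathways:
            child = _pathway_leaf(pgdb, eid, uid, config)
        elif eid in pgdb.pathway_classes:
            child = SubsystemNode(
                uid=f"{uid}/{eid}", name=pgdb.pathway_classes[eid].name,
                abbreviation=abbreviate(pgdb.pathway_classes[eid].name,
                                        config.abbreviations),
                kind="pathway-class", source_ids=(eid,), parent_uid=uid,
                pathway_ids=pgdb.pathways_under_class(eid))
        elif eid in pgdb.go_terms:
            child = SubsystemNode(
                uid=f"{uid}/{eid}", name=pgdb.go_terms[eid].name,
                abbreviation=abbreviate(pgdb.go_terms[eid].name,
                                        config.abbreviations),
                kind="go-term", source_ids=(eid,), parent_uid=uid,
                go_ids=pgdb.go_descendants[eid])
        elif eid in pgdb.genes or eid in pgdb.compounds:
            obj = pgdb.genes.get(eid) or pgdb.compounds[eid]
            child = SubsystemNode(
                uid=f"{uid}/{eid}", name=obj.name,
                abbreviation=abbreviate(obj.name, config.abbreviations),
                kind="custom", source_ids=(eid,), parent_uid=uid,
                entity_ids=frozenset({eid}))
        else:
            raise HierarchyError(f"unknown id {eid!r} in custom panel")
        panel.children.append(child)
    _compute_members(pgdb, panel, bundle, resolution)
    if _prune(panel):
        tree.panels.append(panel)
        tree.reindex()
    return tree


def drill_path(tree: DashboardTree, node_uid: str) -> list[SubsystemNode]:
    """Ordered node list from the panel root down to the node."""
    node = tree.get(node_uid)
    path = [node]
    while node.parent_uid is not None:
        node = tree.get(node.parent_uid)
        path.append(node)
    return list(reversed(path))
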
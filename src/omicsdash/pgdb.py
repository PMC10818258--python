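"""Pathway/genome database (PGDB) model.

An organism's pathway/genome database holds the objects the dashboard is
built from: compounds arranged in a chemical-class DAG (a class such as
"isocitrate" groups instances such as "D-threo-isocitrate"), pathways with
their class memberships and curator-designated primary inputs/outputs,
genes with GO annotations and transport/regulatory activity tags, and the
GO term DAG itself.

The on-disk format is a single versioned JSON document (see
``data/pgdb.schema.json`` for the normative schema).  Loading validates
every cross-reference and every DAG, and builds the derived indexes the
rest of the package queries:

* case-folded name/synonym indexes per namespace (compounds, genes),
* compound -> pathways and gene -> pathways participation maps,
* GO term -> descendant closure and term -> annotated-gene rollups.

The central graph query is :func:`compound_closure`: a dataset row naming
a compound class must match pathways that list one of its instances, and a
row naming an instance must match pathways that list the class, so the
closure runs in *both* directions of the class DAG.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx

SCHEMA_VERSION = 1

#: ids of the four pathway-class roots that become the metabolic panels.
METABOLIC_ROOT_IDS = (
    "Biosynthesis",
    "Degradation",
    "Energy-Metabolism",
    "Other-Pathways",
)

ACTIVITY_TAGS = ("transporter", "regulator")


class PGDBError(Exception):
    """Raised for schema violations, dangling references and DAG cycles.

    ``location`` is a JSON-pointer-style path into the offending document.
    """

    def __init__(self, message: str, location: str = ""):
        self.location = location
        super().__init__(f"{message}" + (f" (at {location})" if location else ""))


@dataclass(frozen=True)
class CompoundNode:
    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    is_class: bool = False


@dataclass(frozen=True)
class PathwayClass:
    id: str
    name: str
    parent_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    class_ids: tuple[str, ...]
    compound_ids: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()
    primary_input_ids: tuple[str, ...] = ()
    primary_output_ids: tuple[str, ...] = ()

    @property
    def primary_ids(self) -> frozenset[str]:
        return frozenset(self.primary_input_ids) | frozenset(self.primary_output_ids)


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    parent_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Gene:
    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    go_term_ids: tuple[str, ...] = ()
    activity_tags: tuple[str, ...] = ()
    product_name: str | None = None
    operon_id: str | None = None


def normalize_name(name: str) -> str:
    """Case-fold and collapse internal whitespace for name matching."""
    return " ".join(name.casefold().split())


def _dag_check(graph: nx.DiGraph, what: str) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path = " -> ".join(str(a) for a, _ in cycle)
        raise PGDBError(f"cycle in {what} hierarchy: {path}", f"/{what}")


@dataclass
class PGDB:
    """Fully indexed pathway/genome database.

    Construct via :func:`load_pgdb` or :func:`pgdb_from_dict`; the
    constructor assumes collections are already validated.
    """

    organism: str
    compounds: dict[str, CompoundNode]
    pathways: dict[str, Pathway]
    pathway_classes: dict[str, PathwayClass]
    go_terms: dict[str, GoTerm]
    genes: dict[str, Gene]

    # derived (built in __post_init__)
    compound_graph: nx.DiGraph = field(init=False, repr=False)
    class_graph: nx.DiGraph = field(init=False, repr=False)
    go_graph: nx.DiGraph = field(init=False, repr=False)
    compound_name_index: dict[str, frozenset[str]] = field(init=False, repr=False)
    compound_synonym_index: dict[str, frozenset[str]] = field(init=False, repr=False)
    gene_name_index: dict[str, frozenset[str]] = field(init=False, repr=False)
    gene_synonym_index: dict[str, frozenset[str]] = field(init=False, repr=False)
    compound_to_pathways: dict[str, frozenset[str]] = field(init=False, repr=False)
    gene_to_pathways: dict[str, frozenset[str]] = field(init=False, repr=False)
    go_descendants: dict[str, frozenset[str]] = field(init=False, repr=False)
    go_to_genes: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # edges point child -> parent in all three DAGs
        self.compound_graph = nx.DiGraph()
        self.compound_graph.add_nodes_from(self.compounds)
        for c in self.compounds.values():
            for p in c.parent_ids:
                self.compound_graph.add_edge(c.id, p)

        self.class_graph = nx.DiGraph()
        self.class_graph.add_nodes_from(self.pathway_classes)
        for pc in self.pathway_classes.values():
            for p in pc.parent_ids:
                self.class_graph.add_edge(pc.id, p)

        self.go_graph = nx.DiGraph()
        self.go_graph.add_nodes_from(self.go_terms)
        for t in self.go_terms.values():
            for p in t.parent_ids:
                self.go_graph.add_edge(t.id, p)

        def name_index(objs, attr):
            idx: dict[str, set[str]] = {}
            for o in objs.values():
                for nm in attr(o):
                    if nm:
                        idx.setdefault(normalize_name(nm), set()).add(o.id)
            return {k: frozenset(v) for k, v in idx.items()}

        self.compound_name_index = name_index(self.compounds, lambda c: [c.name])
        self.compound_synonym_index = name_index(self.compounds, lambda c: c.synonyms)
        self.gene_name_index = name_index(self.genes, lambda g: [g.name])
        self.gene_synonym_index = name_index(
            self.genes, lambda g: list(g.synonyms) + ([g.product_name] if g.product_name else [])
        )

        c2p: dict[str, set[str]] = {}
        g2p: dict[str, set[str]] = {}
        for pwy in self.pathways.values():
            for c in pwy.compound_ids:
                c2p.setdefault(c, set()).add(pwy.id)
            for g in pwy.gene_ids:
                g2p.setdefault(g, set()).add(pwy.id)
        self.compound_to_pathways = {k: frozenset(v) for k, v in c2p.items()}
        self.gene_to_pathways = {k: frozenset(v) for k, v in g2p.items()}

        self.go_descendants = {
            t: frozenset({t} | nx.ancestors(self.go_graph, t)) for t in self.go_terms
        }  # graph edges run child->parent, so graph-ancestors are ontology descendants
        go2g: dict[str, set[str]] = {t: set() for t in self.go_terms}
        for g in self.genes.values():
            for t in g.go_term_ids:
                for anc in {t} | nx.descendants(self.go_graph, t):
                    go2g[anc].add(g.id)
        self.go_to_genes = {k: frozenset(v) for k, v in go2g.items()}

    # -- graph queries -------------------------------------------------

    def compound_closure(self, node_id: str) -> frozenset[str]:
        """The compound plus all class ancestors and all descendants.

        Symmetric expansion over the compound-class DAG: a class covers all
        its instance descendants (a dataset reporting "isocitrate" matches a
        pathway listing D-threo-isocitrate) and an instance is covered by
        its class ancestors (a dataset reporting the instance matches a
        pathway listing the class).
        """
        if node_id not in self.compounds:
            raise PGDBError(f"unknown compound id {node_id!r}")
        g = self.compound_graph
        return frozenset({node_id} | nx.descendants(g, node_id) | nx.ancestors(g, node_id))

    def pathways_of(self, entity_id: str) -> frozenset[str]:
        """Pathways an entity participates in.

        Genes match by direct pathway membership; compounds match any
        pathway listing any member of their class closure.
        """
        if entity_id in self.genes:
            return self.gene_to_pathways.get(entity_id, frozenset())
        if entity_id in self.compounds:
            out: set[str] = set()
            for c in self.compound_closure(entity_id):
                out |= self.compound_to_pathways.get(c, frozenset())
            return frozenset(out)
        raise PGDBError(f"unknown entity id {entity_id!r}")

    def pathway_count(self, compound_id: str) -> int:
        """Number of pathways the compound (closure-expanded) participates in."""
        return len(self.pathways_of(compound_id))

    def class_descendants(self, class_id: str) -> frozenset[str]:
        """The pathway class plus all descendant classes."""
        if class_id not in self.pathway_classes:
            raise PGDBError(f"unknown pathway class {class_id!r}")
        return frozenset({class_id} | nx.ancestors(self.class_graph, class_id))

    def class_children(self, class_id: str) -> list[str]:
        """Direct child classes, sorted by id."""
        return sorted(self.class_graph.predecessors(class_id))

    def pathways_under_class(self, class_id: str) -> frozenset[str]:
        """Pathways attached at the class or any descendant class."""
        classes = self.class_descendants(class_id)
        return frozenset(
            p.id for p in self.pathways.values() if classes.intersection(p.class_ids)
        )


# ---------------------------------------------------------------------------
# loading / validation


def _require(cond: bool, msg: str, loc: str) -> None:
    if not cond:
        raise PGDBError(msg, loc)


def _as_str_tuple(value, loc: str) -> tuple[str, ...]:
    _require(isinstance(value, list) and all(isinstance(v, str) for v in value),
             "expected a list of strings", loc)
    return tuple(value)


def pgdb_from_dict(doc: dict) -> PGDB:
    """Validate a raw JSON document and build the indexed PGDB."""
    _require(isinstance(doc, dict), "document must be a JSON object", "")
    version = doc.get("schema_version")
    _require(version == SCHEMA_VERSION,
             f"schema_version must be {SCHEMA_VERSION}, got {version!r}", "/schema_version")
    organism = doc.get("organism")
    _require(isinstance(organism, str) and organism != "", "organism must be a non-empty string",
             "/organism")

    def parse_collection(key, required, optional, factory):
        items = doc.get(key, [])
        _require(isinstance(items, list), f"{key} must be a list", f"/{key}")
        out = {}
        for i, raw in enumerate(items):
            loc = f"/{key}/{i}"
            _require(isinstance(raw, dict), "expected an object", loc)
            unknown = set(raw) - set(required) - set(optional)
            _require(not unknown, f"unknown fields {sorted(unknown)}", loc)
            for f_ in required:
                _require(f_ in raw, f"missing required field {f_!r}", loc)
            obj = factory(raw, loc)
            _require(obj.id not in out, f"duplicate id {obj.id!r}", f"{loc}/id")
            out[obj.id] = obj
        return out

    def mk_compound(raw, loc):
        _require(isinstance(raw["id"], str), "id must be a string", f"{loc}/id")
        _require(isinstance(raw["name"], str), "name must be a string", f"{loc}/name")
        is_class = raw.get("is_class", False)
        _require(isinstance(is_class, bool), "is_class must be a boolean", f"{loc}/is_class")
        return CompoundNode(
            id=raw["id"], name=raw["name"],
            synonyms=_as_str_tuple(raw.get("synonyms", []), f"{loc}/synonyms"),
            parent_ids=_as_str_tuple(raw.get("parent_ids", []), f"{loc}/parent_ids"),
            is_class=is_class,
        )

    def mk_class(raw, loc):
        return PathwayClass(
            id=raw["id"], name=raw["name"],
            parent_ids=_as_str_tuple(raw.get("parent_ids", []), f"{loc}/parent_ids"),
        )

    def mk_pathway(raw, loc):
        pwy = Pathway(
            id=raw["id"], name=raw["name"],
            class_ids=_as_str_tuple(raw["class_ids"], f"{loc}/class_ids"),
            compound_ids=_as_str_tuple(raw.get("compound_ids", []), f"{loc}/compound_ids"),
            gene_ids=_as_str_tuple(raw.get("gene_ids", []), f"{loc}/gene_ids"),
            primary_input_ids=_as_str_tuple(raw.get("primary_input_ids", []),
                                            f"{loc}/primary_input_ids"),
            primary_output_ids=_as_str_tuple(raw.get("primary_output_ids", []),
                                             f"{loc}/primary_output_ids"),
        )
        _require(len(pwy.class_ids) > 0, "class_ids must be non-empty", f"{loc}/class_ids")
        extra = pwy.primary_ids - set(pwy.compound_ids)
        _require(not extra,
                 f"primary inputs/outputs {sorted(extra)} not among compound_ids", loc)
        return pwy

    def mk_go(raw, loc):
        return GoTerm(
            id=raw["id"], name=raw["name"],
            parent_ids=_as_str_tuple(raw.get("parent_ids", []), f"{loc}/parent_ids"),
        )

    def mk_gene(raw, loc):
        tags = _as_str_tuple(raw.get("activity_tags", []), f"{loc}/activity_tags")
        bad = set(tags) - set(ACTIVITY_TAGS)
        _require(not bad, f"unknown activity tags {sorted(bad)}", f"{loc}/activity_tags")
        return Gene(
            id=raw["id"], name=raw["name"],
            synonyms=_as_str_tuple(raw.get("synonyms", []), f"{loc}/synonyms"),
            go_term_ids=_as_str_tuple(raw.get("go_term_ids", []), f"{loc}/go_term_ids"),
            activity_tags=tags,
            product_name=raw.get("product_name"),
            operon_id=raw.get("operon_id"),
        )

    compounds = parse_collection(
        "compounds", ("id", "name"), ("synonyms", "parent_ids", "is_class"), mk_compound)
    pathway_classes = parse_collection(
        "pathway_classes", ("id", "name"), ("parent_ids",), mk_class)
    pathways = parse_collection(
        "pathways", ("id", "name", "class_ids"),
        ("compound_ids", "gene_ids", "primary_input_ids", "primary_output_ids"), mk_pathway)
    go_terms = parse_collection("go_terms", ("id", "name"), ("parent_ids",), mk_go)
    genes = parse_collection(
        "genes", ("id", "name"),
        ("synonyms", "go_term_ids", "activity_tags", "product_name", "operon_id"), mk_gene)

    # cross-reference checks with JSON-pointer locations
    def check_refs(key, objs, attr, target, what):
        for i, obj in enumerate(objs.values()):
            for ref in getattr(obj, attr):
                _require(ref in target,
                         f"dangling {what} reference {ref!r}", f"/{key}/{i}/{attr}")

    check_refs("compounds", compounds, "parent_ids", compounds, "compound")
    check_refs("pathway_classes", pathway_classes, "parent_ids", pathway_classes,
               "pathway-class")
    check_refs("pathways", pathways, "class_ids", pathway_classes, "pathway-class")
    check_refs("pathways", pathways, "compound_ids", compounds, "compound")
    check_refs("pathways", pathways, "gene_ids", genes, "gene")
    check_refs("go_terms", go_terms, "parent_ids", go_terms, "GO-term")
    check_refs("genes", genes, "go_term_ids", go_terms, "GO-term")

    pgdb = PGDB(organism=organism, compounds=compounds, pathways=pathways,
                pathway_classes=pathway_classes, go_terms=go_terms, genes=genes)

    _dag_check(pgdb.compound_graph, "compounds")
    _dag_check(pgdb.class_graph, "pathway_classes")
    _dag_check(pgdb.go_graph, "go_terms")
    return pgdb


def load_pgdb(path: str | os.PathLike) -> PGDB:
    """Load, validate and index a PGDB JSON file."""
    if not os.path.exists(path):
        raise PGDBError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise PGDBError(f"invalid JSON: {e}") from e
    return pgdb_from_dict(doc)


def pgdb_to_dict(pgdb: PGDB) -> dict:
    """Serialize back to the on-disk JSON document form."""

    def clean(d: dict) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in d.items() if v not in (None, (), [])}

    return {
        "schema_version": SCHEMA_VERSION,
        "organism": pgdb.organism,
        "compounds": [clean(vars(c)) for c in pgdb.compounds.values()],
        "pathway_classes": [clean(vars(c)) for c in pgdb.pathway_classes.values()],
        "pathways": [clean(vars(p)) for p in pgdb.pathways.values()],
        "go_terms": [clean(vars(t)) for t in pgdb.go_terms.values()],
        "genes": [clean(vars(g)) for g in pgdb.genes.values()],
    }


# convenience module-level wrappers mirroring the query surface

def compound_closure(pgdb: PGDB, node_id: str) -> frozenset[str]:
    return pgdb.compound_closure(node_id)


def pathways_of(pgdb: PGDB, entity_id: str) -> frozenset[str]:
    return pgdb.pathways_of(entity_id)


def pathway_count(pgdb: PGDB, compound_id: str) -> int:
    return pgdb.pathway_count(compound_id)
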
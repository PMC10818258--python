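"""Resolution of dataset rows against the PGDB and subsystem membership.

Metabolomics rows resolve against the compound namespace; transcriptomics,
proteomics and flux rows against the gene namespace (proteins are handled
through their genes' names, synonyms and product names).  Matching is
exact-id first, then case-folded name, then synonym; all matches are
retained — an ambiguous row contributes to the union of its matches'
memberships, but appears at most once per plot.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GENE_DATATYPES, OmicsBundle, OmicsDataset
from .pgdb import PGDB, normalize_name


@dataclass(frozen=True)
class ResolvedEntity:
    """Outcome of resolving one dataset row."""

    dataset_index: int
    row_index: int
    entity_name: str
    entity_class: str            # "compound" | "gene"
    match_kind: str              # "id" | "name" | "synonym" | "none"
    matched_ids: tuple[str, ...]

    @property
    def row_key(self) -> tuple[int, int]:
        return (self.dataset_index, self.row_index)


def _namespace(datatype: str) -> str:
    return "gene" if datatype in GENE_DATATYPES else "compound"


def resolve(pgdb: PGDB, dataset: OmicsDataset,
            dataset_index: int = 0) -> list[ResolvedEntity]:
    """Resolve every row of one dataset; unmatched rows get ``none``."""
    ns = _namespace(dataset.datatype)
    if ns == "compound":
        ids, name_idx, syn_idx = (pgdb.compounds, pgdb.compound_name_index,
                                  pgdb.compound_synonym_index)
    else:
        ids, name_idx, syn_idx = (pgdb.genes, pgdb.gene_name_index,
                                  pgdb.gene_synonym_index)
    out = []
    for r, (name, _) in enumerate(dataset.rows):
        key = normalize_name(name)
        if name in ids:
            kind, matched = "id", (name,)
        elif key in name_idx:
            kind, matched = "name", tuple(sorted(name_idx[key]))
        elif key in syn_idx:
            kind, matched = "synonym", tuple(sorted(syn_idx[key]))
        else:
            kind, matched = "none", ()
        out.append(ResolvedEntity(dataset_index=dataset_index, row_index=r,
                                  entity_name=name, entity_class=ns,
                                  match_kind=kind, matched_ids=matched))
    return out


def resolve_bundle(pgdb: PGDB, bundle: OmicsBundle) -> dict[int, list[ResolvedEntity]]:
    """Resolve every dataset in a bundle, keyed by dataset index."""
    return {i: resolve(pgdb, ds, i) for i, ds in enumerate(bundle.datasets)}


def row_pathways(pgdb: PGDB, entity: ResolvedEntity) -> frozenset[str]:
    """All pathways any matched id of the row participates in."""
    out: set[str] = set()
    for mid in entity.matched_ids:
        out |= pgdb.pathways_of(mid)
    return frozenset(out)


def members(pgdb: PGDB, node, bundle: OmicsBundle,
            resolution: dict[int, list[ResolvedEntity]]) -> dict[int, list[int]]:
    """Rows belonging to a subsystem node, per dataset.

    Pathway-backed nodes (pathway, pathway-class, other-bucket, custom
    pathway lists) admit compound rows whose closure-expanded pathway set
    intersects the node's pathways, and gene rows listed as enzymes of
    those pathways.  GO-backed nodes admit gene rows annotated to the
    node's terms or any descendant term; activity nodes admit gene rows
    carrying the tag.  Returns sorted row indices per dataset index.

    ``node`` must expose ``pathway_ids``, ``go_ids`` (descendant-closed),
    ``activity_tag`` and ``entity_ids`` as computed by the hierarchy
    builder.
    """
    pwy_ids: frozenset[str] = node.pathway_ids
    go_ids: frozenset[str] = node.go_ids
    tag: str | None = node.activity_tag
    explicit: frozenset[str] = node.entity_ids

    go_genes: set[str] = set()
    for t in go_ids:
        go_genes |= pgdb.go_to_genes.get(t, frozenset())
    pwy_genes: set[str] = set()
    for p in pwy_ids:
        pwy_genes |= set(pgdb.pathways[p].gene_ids)

    out: dict[int, list[int]] = {}
    for ds_idx, entities in resolution.items():
        hits = []
        for ent in entities:
            if ent.match_kind == "none":
                continue
            if ent.entity_class == "compound":
                if pwy_ids and row_pathways(pgdb, ent) & pwy_ids:
                    hits.append(ent.row_index)
                elif explicit & set(ent.matched_ids):
                    hits.append(ent.row_index)
            else:
                matched = set(ent.matched_ids)
                if (matched & pwy_genes) or (matched & go_genes) \
                        or (tag and any(tag in pgdb.genes[g].activity_tags
                                        for g in matched)) \
                        or (matched & explicit):
                    hits.append(ent.row_index)
        if hits:
            out[ds_idx] = sorted(set(hits))
    return out


def unmapped(pgdb: PGDB, bundle: OmicsBundle, tree) -> list[tuple[int, int]]:
    """Rows that belong to no subsystem node of the tree.

    Includes unmatched rows and matched entities that sit in no pathway
    and carry no dashboard-relevant annotation.  Together with the union
    of all node member sets this partitions the bundle's rows.
    """
    covered: set[tuple[int, int]] = set()
    for node in tree.walk():
        for ds_idx, rows in node.members.items():
            covered.update((ds_idx, r) for r in rows)
    return [key for key in bundle.all_row_keys() if key not in covered]
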
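"""Synthetic pathway databases and omics datasets with known ground truth.

Every structural quantity a test asserts against (pathway counts per
compound, closure-expanded participant sets, which rows cannot map) is
recorded in a *manifest* computed by brute force from the raw dictionaries
— independently of the indexed PGDB — so module outputs can be checked
against constructed truth.

The generated dataset shapes mirror common metabolomics study designs: a
single treatment-vs-control log fold-change file; a combined multi-omics
file with six metabolomics timepoints (absolute normalized abundances)
plus two transcriptomics log-ratio columns; and a replicate-structured
file for averaging.  Relative values in designated "responsive"
subsystems are drawn from Normal(effect, 1) and from Normal(0, 1)
elsewhere, giving visually drillable fixtures with standout subsystems.
All randomness flows from one integer seed through a single generator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import io
from .hierarchy import DashboardConfig
from .pgdb import METABOLIC_ROOT_IDS, PGDB, pgdb_from_dict


class FixtureError(Exception):
    pass


@dataclass
class FixtureSpec:
    """Knobs of the generator; defaults give a compact but full-featured
    fixture (all four metabolic panels, Other buckets, class compounds,
    hubs above the common-metabolite threshold, GO rollup, activity tags).
    """

    seed: int = 0
    n_pathways_per_class: int = 3
    compound_class_depth: int = 2
    n_hub_compounds: int = 3
    hub_pathway_count: int = 12
    n_go_groups: int = 2
    n_genes_per_go_term: int = 2
    # dataset shape
    n_metabolomics_rows: int = 60
    n_transcriptomics_rows: int = 40
    n_timepoints: int = 6
    unmapped_fraction: float = 0.1
    fraction_missing: float = 0.05
    effect_size: float = 3.0
    n_replicates: int = 3
    n_conditions: int = 2

    def __post_init__(self):
        if min(self.n_pathways_per_class, self.n_hub_compounds,
               self.n_go_groups, self.compound_class_depth) < 0:
            raise FixtureError("counts must be non-negative")


@dataclass
class FixturePGDB:
    pgdb: PGDB
    raw: dict
    config: DashboardConfig
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# brute-force oracles over the raw document (independent of pgdb indexes)


def brute_force_closure(parents: dict[str, list[str]], node: str) -> set[str]:
    """Transitive closure of ``node`` in both directions of the DAG."""
    children: dict[str, set[str]] = {}
    for c, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(c)
    out = {node}
    frontier = [node]
    while frontier:  # up
        cur = frontier.pop()
        for p in parents.get(cur, []):
            if p not in out:
                out.add(p)
                frontier.append(p)
    up = set(out)
    frontier = [node]
    seen_down = {node}
    while frontier:  # down
        cur = frontier.pop()
        for c in children.get(cur, ()):
            if c not in seen_down:
                seen_down.add(c)
                frontier.append(c)
    return up | seen_down


def brute_force_pathway_counts(raw: dict) -> dict[str, int]:
    """Per-compound pathway counts by linear scan with closure expansion."""
    parents = {c["id"]: list(c.get("parent_ids", [])) for c in raw["compounds"]}
    counts = {}
    for c in raw["compounds"]:
        closure = brute_force_closure(parents, c["id"])
        n = 0
        for p in raw["pathways"]:
            if closure.intersection(p.get("compound_ids", [])):
                n += 1
        counts[c["id"]] = n
    return counts


# ---------------------------------------------------------------------------
# PGDB construction


def make_pgdb(spec: FixtureSpec) -> FixturePGDB:
    """Build a synthetic PGDB plus its ground-truth manifest and a matching
    dashboard configuration."""
    n = spec.n_pathways_per_class
    compounds: list[dict] = []
    classes: list[dict] = []
    pathways: list[dict] = []
    genes: list[dict] = []
    go_terms: list[dict] = []
    seen_cpds: set[str] = set()

    def add_compound(cid, name=None, parent_ids=(), is_class=False, synonyms=()):
        if cid in seen_cpds:
            return
        seen_cpds.add(cid)
        compounds.append({"id": cid, "name": name or cid.replace("-", " "),
                          "synonyms": list(synonyms),
                          "parent_ids": list(parent_ids),
                          "is_class": is_class})

    hub_ids = [f"hub-{k + 1}" for k in range(spec.n_hub_compounds)]
    for hid in hub_ids:
        add_compound(hid, synonyms=[hid.upper()])

    pwy_counter = 0
    curated: dict[str, list[str]] = {}
    responsive: list[str] = []

    def add_pathway(class_id: str, root: str) -> str:
        nonlocal pwy_counter
        pwy_counter += 1
        pid = f"pwy-{pwy_counter:03d}"
        cids = [f"cpd-{pid}-{x}" for x in "abc"]
        for cid in cids:
            add_compound(cid)
        participants = list(cids)
        # a class-compound scenario on the first pathway of each root:
        # the pathway lists an instance, datasets may name the class
        if class_id.endswith("-deep"):
            chain_top = f"class-{pid}"
            prev = chain_top
            add_compound(chain_top, is_class=True)
            for d in range(1, spec.compound_class_depth):
                nxt = f"class-{pid}-l{d}"
                add_compound(nxt, parent_ids=[prev], is_class=True)
                prev = nxt
            iso1 = f"iso-{pid}-1"
            iso2 = f"iso-{pid}-2"
            add_compound(iso1, parent_ids=[prev])
            add_compound(iso2, parent_ids=[prev])
            participants.append(iso1)
        gids = [f"gene-{pid}-1", f"gene-{pid}-2"]
        for gid in gids:
            genes.append({"id": gid, "name": gid.replace("-", " "),
                          "synonyms": [gid.upper()],
                          "go_term_ids": [], "activity_tags": [],
                          "product_name": f"{gid} product",
                          "operon_id": f"op-{pid}"})
        pathways.append({"id": pid, "name": f"pathway {pwy_counter:03d}"
                         f" ({class_id})",
                         "class_ids": [class_id],
                         "compound_ids": participants, "gene_ids": gids,
                         "primary_input_ids": [participants[0]],
                         "primary_output_ids": [participants[len(cids) - 1]]})
        return pid

    for root in METABOLIC_ROOT_IDS:
        classes.append({"id": root, "name": root.replace("-", " "),
                        "parent_ids": []})
        sub1, sub2, misc = f"{root}-sub1", f"{root}-sub2", f"{root}-misc"
        deep = f"{sub1}-deep"
        for cid, parent in ((sub1, root), (sub2, root), (misc, root),
                            (deep, sub1)):
            classes.append({"id": cid, "name": cid.replace("-", " "),
                            "parent_ids": [parent]})
        curated[root] = [sub1, sub2]
        curated[sub1] = [deep]
        if n > 0:
            first = add_pathway(deep, root)
            if root == "Biosynthesis":
                responsive.append(first)
            for _ in range(n - 1):
                add_pathway(deep, root)
            add_pathway(sub1, root)  # attached directly at a curated class
            for _ in range(n):
                add_pathway(sub2, root)
            for _ in range(n):
                add_pathway(misc, root)

    # place hub compounds in many pathways, primary output of their first host
    if hub_ids:
        if spec.hub_pathway_count > len(pathways):
            raise FixtureError(
                f"hub compounds need {spec.hub_pathway_count} pathways but only"
                f" {len(pathways)} exist")
        for k, hid in enumerate(hub_ids):
            hosts = [pathways[(k + 3 * j) % len(pathways)]
                     for j in range(spec.hub_pathway_count)]
            hosts_seen = []
            for h in hosts:
                if h["id"] not in hosts_seen:
                    hosts_seen.append(h["id"])
                    h["compound_ids"].append(hid)
            while len(hosts_seen) < spec.hub_pathway_count:
                extra = next(p for p in pathways if p["id"] not in hosts_seen)
                extra["compound_ids"].append(hid)
                hosts_seen.append(extra["id"])
            first_host = next(p for p in pathways if p["id"] == hosts_seen[0])
            first_host["primary_output_ids"].append(hid)

    # orphan objects that can resolve but map nowhere
    add_compound("orphan-cpd")
    genes.append({"id": "orphan-gene", "name": "orphan gene", "synonyms": [],
                  "go_term_ids": [], "activity_tags": [],
                  "product_name": None, "operon_id": None})

    # GO groups: parent term with two children; genes annotated to children
    go_panels: dict[str, dict[str, list[str]]] = {}
    panel_cycle = ("Central-Dogma", "Response-to-Stimulus",
                   "Cellular-Processes", "Virulence-Related", "Cell-Exterior")
    for g in range(1, spec.n_go_groups + 1):
        parent = f"go:{g:04d}"
        go_terms.append({"id": parent, "name": f"go group {g}",
                         "parent_ids": []})
        for c in (1, 2):
            child = f"go:{g:04d}.{c}"
            go_terms.append({"id": child, "name": f"go term {g}.{c}",
                             "parent_ids": [parent]})
            for k in range(spec.n_genes_per_go_term):
                gid = f"gogene-{g}-{c}-{k + 1}"
                genes.append({"id": gid, "name": gid.replace("-", " "),
                              "synonyms": [], "go_term_ids": [child],
                              "activity_tags": [], "product_name": None,
                              "operon_id": None})
        panel = panel_cycle[(g - 1) % len(panel_cycle)]
        go_panels.setdefault(panel, {})[f"group-{g}"] = [parent]
    for tag, gid in (("transporter", "tr-gene-1"), ("transporter", "tr-gene-2"),
                     ("regulator", "reg-gene-1")):
        genes.append({"id": gid, "name": gid.replace("-", " "), "synonyms": [],
                      "go_term_ids": [], "activity_tags": [tag],
                      "product_name": None, "operon_id": None})

    raw = {"schema_version": 1, "organism": "Syntheticus exemplaris",
           "compounds": compounds, "pathway_classes": classes,
           "pathways": pathways, "go_terms": go_terms, "genes": genes}
    pgdb = pgdb_from_dict(raw)

    config = DashboardConfig(
        flatten_depth=3, curated_classes=curated, go_panels=go_panels,
        activity_panels={"Cell-Exterior": ["transporter"],
                         "Central-Dogma": ["regulator"]})

    parents = {c["id"]: list(c["parent_ids"]) for c in compounds}
    manifest = {
        "n_pathways": len(pathways),
        "pathway_counts": brute_force_pathway_counts(raw),
        "hub_ids": hub_ids,
        "responsive_pathways": responsive,
        "pathway_participants_expanded": {
            p["id"]: sorted(set().union(*[
                brute_force_closure(parents, c) for c in p["compound_ids"]]))
            for p in pathways},
    }
    return FixturePGDB(pgdb=pgdb, raw=raw, config=config, manifest=manifest)


def write_pgdb(fx: FixturePGDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fx.raw, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# dataset construction


@dataclass
class FixtureData:
    """Generated datasets plus the truths tests assert against."""

    single: io.OmicsDataset
    bundle: io.OmicsBundle
    replicates: io.OmicsDataset
    unmapped_names: list[str]
    responsive_names: set[str]
    paths: dict[str, str] = field(default_factory=dict)


def _pick_names(rng, pool: list[str], k: int) -> list[str]:
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def make_dataset(fx: FixturePGDB, spec: FixtureSpec,
                 out_dir: str | None = None) -> FixtureData:
    """Generate the three dataset shapes for a fixture PGDB.

    Metabolomics rows are drawn from the PGDB's compound *names* (classes
    and instances both occur), transcriptomics rows from gene names, and
    ``unmapped_fraction`` of rows get names absent from the database.
    """
    pgdb = fx.pgdb
    if not pgdb.pathways:
        raise FixtureError("cannot generate datasets for an empty PGDB")
    rng = np.random.default_rng(spec.seed)

    responsive_cpds: set[str] = set()
    responsive_genes: set[str] = set()
    for pid in fx.manifest["responsive_pathways"]:
        pwy = pgdb.pathways[pid]
        for cid in pwy.compound_ids:
            responsive_cpds |= pgdb.compound_closure(cid)
        responsive_genes |= set(pwy.gene_ids)
    hub_ids = set(fx.manifest["hub_ids"])

    cpd_pool = sorted(c.name for c in pgdb.compounds.values()
                      if c.id not in hub_ids)
    gene_pool = sorted(g.name for g in pgdb.genes.values())
    responsive_names = ({pgdb.compounds[c].name for c in responsive_cpds
                         if c in pgdb.compounds}
                        | {pgdb.genes[g].name for g in responsive_genes})

    n_unmapped_m = round(spec.unmapped_fraction * spec.n_metabolomics_rows)
    n_mapped_m = spec.n_metabolomics_rows - n_unmapped_m
    hub_names = sorted(pgdb.compounds[h].name for h in hub_ids)
    met_names = (hub_names
                 + _pick_names(rng, cpd_pool, n_mapped_m - len(hub_names))
                 + [f"unknown-met-{i + 1}" for i in range(n_unmapped_m)])
    unmapped_names = [f"unknown-met-{i + 1}" for i in range(n_unmapped_m)]

    def draw(name: str, relative: bool) -> float:
        loc = spec.effect_size if name in responsive_names else 0.0
        v = rng.normal(loc, 1.0)
        return v if relative else float(np.exp(0.3 * v + 4.0))

    def maybe_missing() -> bool:
        return bool(rng.random() < spec.fraction_missing)

    # (a) single-condition metabolomics log fold-change + p-value column
    rows_a = []
    for name in met_names:
        v = None if maybe_missing() else draw(name, relative=True)
        p = float(rng.uniform(0, 0.04)) if name in responsive_names \
            else float(rng.uniform(0, 1))
        rows_a.append((name, {1: v, 2: round(p, 6)}))
    single = io.OmicsDataset(
        datatype="metabolomics", value_scale="relative", log_transformed=True,
        column_specs=[io.ColumnSpec(1, "log2FC", "data"),
                      io.ColumnSpec(2, "pval", "significance",
                                    significance_for=1)],
        rows=rows_a)

    # (b) combined multi-omics: 6 metabolomics timepoints (absolute) +
    #     2 transcriptomics log-ratio columns with significance columns
    tp_labels = [f"t{8 * (i + 1)}h" for i in range(spec.n_timepoints)]
    rows_m = []
    for name in met_names:
        vals: dict[int, float | None] = {}
        for i in range(spec.n_timepoints):
            vals[i + 1] = None if maybe_missing() else \
                round(draw(name, relative=False), 4)
        rows_m.append((name, vals))
    met_ds = io.OmicsDataset(
        datatype="metabolomics", value_scale="absolute",
        column_specs=[io.ColumnSpec(i + 1, tp_labels[i], "data")
                      for i in range(spec.n_timepoints)],
        rows=rows_m)

    n_unmapped_t = round(spec.unmapped_fraction * spec.n_transcriptomics_rows)
    n_mapped_t = spec.n_transcriptomics_rows - n_unmapped_t
    # activity-tagged and orphan genes always present so the corresponding
    # subsystems (and the not-in-any-subsystem panel) are exercised
    special = ["tr gene 1", "reg gene 1", "orphan gene"]
    pool_t = [g for g in gene_pool if g not in special]
    gene_names = (special
                  + _pick_names(rng, pool_t, n_mapped_t - len(special))
                  + [f"unknown-gene-{i + 1}" for i in range(n_unmapped_t)])
    unmapped_names += [f"unknown-gene-{i + 1}" for i in range(n_unmapped_t)]
    rows_t = []
    for name in gene_names:
        vals = {}
        for i in (1, 2):
            vals[i] = None if maybe_missing() else round(draw(name, True), 4)
            vals[i + 2] = round(float(rng.uniform(0, 0.05))
                                if name in responsive_names
                                else float(rng.uniform(0, 1)), 6)
        rows_t.append((name, vals))
    trn_ds = io.OmicsDataset(
        datatype="transcriptomics", value_scale="relative",
        log_transformed=True,
        column_specs=[io.ColumnSpec(1, "lfc_16v24", "data"),
                      io.ColumnSpec(2, "lfc_24v48", "data"),
                      io.ColumnSpec(3, "p_16v24", "significance",
                                    significance_for=1),
                      io.ColumnSpec(4, "p_24v48", "significance",
                                    significance_for=2)],
        rows=rows_t)
    bundle = io.OmicsBundle(datasets=[met_ds, trn_ds])

    # (c) replicate-structured single-omics file
    rep_specs = []
    idx = 1
    for c in range(spec.n_conditions):
        for r in range(spec.n_replicates):
            rep_specs.append(io.ColumnSpec(idx, f"c{c + 1}_r{r + 1}", "data"))
            idx += 1
    rep_rows = []
    for name in met_names[: max(10, spec.n_metabolomics_rows // 2)]:
        vals = {}
        for c in rep_specs:
            vals[c.index] = None if maybe_missing() else \
                round(draw(name, relative=False), 4)
        rep_rows.append((name, vals))
    replicates = io.OmicsDataset(datatype="metabolomics",
                                 value_scale="absolute",
                                 column_specs=rep_specs, rows=rep_rows)

    fd = FixtureData(single=single, bundle=bundle, replicates=replicates,
                     unmapped_names=unmapped_names,
                     responsive_names=responsive_names)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        fd.paths = {
            "pgdb": os.path.join(out_dir, "pgdb.json"),
            "single": os.path.join(out_dir, "metabolomics_lfc.tsv"),
            "combined": os.path.join(out_dir, "multiomics_combined.tsv"),
            "replicates": os.path.join(out_dir, "metabolomics_replicates.tsv"),
            "manifest": os.path.join(out_dir, "manifest.json"),
        }
        write_pgdb(fx, fd.paths["pgdb"])
        io.write_dataset(single, fd.paths["single"])
        io.write_bundle(bundle, fd.paths["combined"])
        io.write_dataset(replicates, fd.paths["replicates"])
        with open(fd.paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(fx.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return fd


def make_fixture(seed: int = 0, out_dir: str | None = None,
                 **overrides) -> tuple[FixturePGDB, FixtureData]:
    """One-call fixture: PGDB + config + datasets (+ files when out_dir)."""
    spec = FixtureSpec(seed=seed, **overrides)
    fx = make_pgdb(spec)
    fd = make_dataset(fx, spec, out_dir=out_dir)
    return fx, fd
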
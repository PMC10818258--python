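"""Shared fixtures: the standard synthetic environment and a hand-written
miniature database for the stereoisomer-matching scenario."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import omicsdash as od


@pytest.fixture(scope="session")
def env():
    """Standard fixture environment: PGDB + multi-omics bundle + tree."""
    fx, fd = od.make_fixture(seed=0)
    tree = od.build_tree(fx.pgdb, fd.bundle, fx.config)
    outcome = od.apply_filters(fx.pgdb, fd.bundle, tree, od.no_filters())
    axes = od.assign_axes(fd.bundle)
    return SimpleNamespace(fx=fx, fd=fd, pgdb=fx.pgdb, bundle=fd.bundle,
                           config=fx.config, tree=tree, outcome=outcome,
                           axes=axes, manifest=fx.manifest)


def tca_raw() -> dict:
    """A minimal database: the class compound "isocitrate" groups the
    instance "D-threo-isocitrate", which participates in a TCA-like cycle
    filed under Energy Metabolism."""
    return {
        "schema_version": 1,
        "organism": "mini",
        "compounds": [
            {"id": "ISOCITRATE", "name": "isocitrate", "is_class": True},
            {"id": "D-THREO-ISOCITRATE", "name": "D-threo-isocitrate",
             "parent_ids": ["ISOCITRATE"]},
            {"id": "CIT", "name": "citrate"},
            {"id": "MAL", "name": "malate", "synonyms": ["(S)-malate"]},
            {"id": "GLT", "name": "2-oxoglutarate"},
            {"id": "LONELY", "name": "lonely compound"},
        ],
        "pathway_classes": [
            {"id": "Biosynthesis", "name": "Biosynthesis"},
            {"id": "Degradation", "name": "Degradation"},
            {"id": "Energy-Metabolism", "name": "Energy Metabolism"},
            {"id": "Other-Pathways", "name": "Other Pathways"},
            {"id": "TCA-VARIANTS", "name": "TCA cycle variants",
             "parent_ids": ["Energy-Metabolism"]},
        ],
        "pathways": [
            {"id": "TCA", "name": "TCA cycle", "class_ids": ["TCA-VARIANTS"],
             "compound_ids": ["CIT", "D-THREO-ISOCITRATE", "GLT", "MAL"],
             "gene_ids": ["acnB"],
             "primary_input_ids": ["CIT"], "primary_output_ids": ["MAL"]},
        ],
        "go_terms": [],
        "genes": [{"id": "acnB", "name": "acnB",
                   "synonyms": ["aconitase B"], "go_term_ids": [],
                   "activity_tags": []}],
    }


@pytest.fixture()
def tca_pgdb():
    return od.pgdb_from_dict(tca_raw())


def make_metabolomics(rows, n_cols=1, labels=None):
    """In-memory single-column metabolomics dataset from (name, values)."""
    labels = labels or [f"c{i + 1}" for i in range(n_cols)]
    specs = [od.ColumnSpec(i + 1, labels[i], "data") for i in range(n_cols)]
    return od.OmicsDataset(datatype="metabolomics", value_scale="relative",
                           log_transformed=True, column_specs=specs,
                           rows=rows)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def matrix_closure(n_nodes: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Boolean reachability matrix by iterated squaring (both directions
    are obtained by using the matrix and its transpose)."""
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for a, b in edges:
        adj[a, b] = True
    reach = adj | np.eye(n_nodes, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            return reach
        reach = nxt


def brute_resolve_compound(raw: dict, name: str) -> tuple[str, list[str]]:
    """Exhaustive scan over ids, names and synonyms of raw compounds."""
    key = " ".join(name.casefold().split())
    ids = [c["id"] for c in raw["compounds"] if c["id"] == name]
    if ids:
        return "id", ids
    ids = [c["id"] for c in raw["compounds"]
           if " ".join(c["name"].casefold().split()) == key]
    if ids:
        return "name", sorted(ids)
    ids = [c["id"] for c in raw["compounds"]
           if any(" ".join(s.casefold().split()) == key
                  for s in c.get("synonyms", []))]
    if ids:
        return "synonym", sorted(ids)
    return "none", []
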
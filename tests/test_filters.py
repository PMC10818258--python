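"""Filter semantics: per-entity inclusion, conjunction, common metabolites."""

import numpy as np
import pytest

import omicsdash as od
from omicsdash.filters import (CommonMetaboliteFilter, FilterConfig,
                               FilterError, SignificanceFilter, ValueFilter,
                               significance_pass, value_pass)

from conftest import make_metabolomics


def random_bundle(rng, n_rows, n_cols, with_sig=True):
    specs = [od.ColumnSpec(i + 1, f"d{i}", "data") for i in range(n_cols)]
    if with_sig:
        specs += [od.ColumnSpec(n_cols + i + 1, f"s{i}", "significance",
                                significance_for=i + 1)
                  for i in range(n_cols)]
    rows = []
    for r in range(n_rows):
        vals = {}
        for c in specs:
            if rng.random() < 0.1:
                vals[c.index] = None
            elif c.role == "data":
                vals[c.index] = float(rng.normal(0, 2))
            else:
                vals[c.index] = float(rng.uniform(0, 1))
        rows.append((f"row-{r}", vals))
    ds = od.OmicsDataset(datatype="metabolomics", value_scale="relative",
                         log_transformed=True, column_specs=specs, rows=rows)
    return od.OmicsBundle(datasets=[ds])


def brute_value_pass(bundle, row, vf, visible):
    ds_idx, r = row
    ok = False
    for (d, c) in visible:
        if d != ds_idx:
            continue
        v = bundle.datasets[d].value(r, c)
        if v is None:
            continue
        x = abs(v) if vf.use_absolute_value else v
        if (vf.direction == "min" and x >= vf.threshold) or \
                (vf.direction == "max" and x <= vf.threshold):
            ok = True
    return ok


def test_absolute_value_filter_catches_negative_changes():
    ds = make_metabolomics([("a", {1: -2.5, 2: 0.1})], n_cols=2)
    bundle = od.OmicsBundle(datasets=[ds])
    vf = ValueFilter(2.0, "min", use_absolute_value=True)
    assert value_pass(bundle, (0, 0), vf, bundle.display_order)
    assert not value_pass(bundle, (0, 0), ValueFilter(2.0, "min", False),
                          bundle.display_order)


def test_all_missing_row_fails_value_filter():
    ds = make_metabolomics([("a", {1: None})])
    bundle = od.OmicsBundle(datasets=[ds])
    assert not value_pass(bundle, (0, 0), ValueFilter(0.0, "min"),
                          bundle.display_order)


def test_value_and_significance_against_brute_force_grid():
    """Randomized rows x thresholds x directions agree with per-cell
    brute-force evaluation."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        bundle = random_bundle(rng, int(rng.integers(5, 60)),
                               int(rng.integers(1, 4)))
        visible = list(bundle.display_order)
        if rng.random() < 0.3 and len(visible) > 1:
            visible = visible[:-1]  # hide one column
        thr = float(rng.normal(0, 2))
        for direction in ("min", "max"):
            for use_abs in (False, True):
                vf = ValueFilter(thr, direction, use_abs)
                for row in bundle.all_row_keys():
                    assert value_pass(bundle, row, vf, visible) == \
                        brute_value_pass(bundle, row, vf, visible)
        sf = SignificanceFilter(float(rng.uniform(0, 1)), "max")
        cmap = sf.resolved_map(bundle)
        for row in bundle.all_row_keys():
            d, r = row
            expect = any(
                bundle.datasets[d].value(r, cmap[k]) is not None
                and bundle.datasets[d].value(r, cmap[k]) <= sf.threshold
                for k in visible if k in cmap and k[0] == d)
            assert significance_pass(bundle, row, sf, visible) == expect


def test_unmapped_significance_column_not_considered():
    """Only data columns with a mapped significance column count."""
    specs = [od.ColumnSpec(1, "d1", "data"), od.ColumnSpec(2, "d2", "data"),
             od.ColumnSpec(3, "p1", "significance", significance_for=1)]
    ds = od.OmicsDataset(datatype="metabolomics", value_scale="relative",
                         column_specs=specs,
                         rows=[("a", {1: 9.0, 2: 9.0, 3: 0.2})])
    bundle = od.OmicsBundle(datasets=[ds])
    sf = SignificanceFilter(0.05, "max")
    # column 1's p=0.2 fails; column 2 has no significance column at all
    assert not significance_pass(bundle, (0, 0), sf, bundle.display_order)
    assert significance_pass(bundle, (0, 0), SignificanceFilter(0.25, "max"),
                             bundle.display_order)


def test_missing_significance_value_cannot_pass():
    specs = [od.ColumnSpec(1, "d", "data"),
             od.ColumnSpec(2, "p", "significance", significance_for=1)]
    ds = od.OmicsDataset(datatype="metabolomics", value_scale="relative",
                         column_specs=specs, rows=[("a", {1: 1.0, 2: None})])
    bundle = od.OmicsBundle(datasets=[ds])
    assert not significance_pass(bundle, (0, 0),
                                 SignificanceFilter(1.0, "max"),
                                 bundle.display_order)


# -- common metabolites -----------------------------------------------------


def test_common_candidates_are_the_hubs(env):
    cands = od.common_candidates(env.pgdb, env.bundle, env.tree.resolution,
                                 threshold=10)
    assert {cid for cid, _ in cands} == set(env.manifest["hub_ids"])
    counts = dict(cands)
    for hid in env.manifest["hub_ids"]:
        assert counts[hid] == env.manifest["pathway_counts"][hid]
    # sorted by count desc
    values = [n for _, n in cands]
    assert values == sorted(values, reverse=True)


def test_common_candidates_threshold_one_lists_every_participant(env):
    cands = od.common_candidates(env.pgdb, env.bundle, env.tree.resolution, 1)
    ids = {cid for cid, _ in cands}
    for ds_idx, ents in env.tree.resolution.items():
        if env.bundle.datasets[ds_idx].datatype != "metabolomics":
            continue
        for e in ents:
            for cid in e.matched_ids:
                if env.pgdb.pathway_count(cid) >= 1:
                    assert cid in ids


def test_common_filter_requires_metabolomics(env):
    trn = env.bundle.datasets[1]
    solo = od.OmicsDataset(datatype=trn.datatype, value_scale=trn.value_scale,
                           column_specs=trn.column_specs, rows=list(trn.rows),
                           log_transformed=trn.log_transformed)
    bundle = od.OmicsBundle(datasets=[solo])
    with pytest.raises(FilterError, match="metabolomics"):
        od.common_candidates(env.pgdb, bundle,
                             od.resolve_bundle(env.pgdb, bundle))


def hub_row(env, hid):
    name = env.pgdb.compounds[hid].name
    ds = env.bundle.datasets[0]
    for r in range(len(ds.rows)):
        if ds.entity_name(r) == name:
            return (0, r)
    raise AssertionError("hub row missing from fixture dataset")


def qualifying_pathways(env, hid):
    return {p.id for p in env.pgdb.pathways.values()
            if env.pgdb.compound_closure(hid) & p.primary_ids}


def test_excluded_hub_survives_only_in_primary_io_lineage(env):
    """An excluded hub stays in pathways where it is a primary output and
    in every ancestor of those pathways, and nowhere else."""
    hid = env.manifest["hub_ids"][0]
    row = hub_row(env, hid)
    cfg = FilterConfig(common_metabolite_filter=CommonMetaboliteFilter(
        10, frozenset({hid})))
    outcome = od.apply_filters(env.pgdb, env.bundle, env.tree, cfg)
    qual = qualifying_pathways(env, hid)
    assert qual, "fixture designates the hub a primary output somewhere"
    for node in env.tree.walk():
        had = row in node.member_row_keys()
        has = row in set(outcome.member_row_keys(node.uid))
        if not had:
            assert not has
        elif node.pathway_ids & qual:
            assert has, f"{node.uid} contains a qualifying pathway"
        else:
            assert not has, f"{node.uid} should hide the excluded hub"


def test_base_node_exclusion_counts_equal_member_difference(env):
    hid = env.manifest["hub_ids"][0]
    cfg = FilterConfig(
        value_filter=ValueFilter(60.0, "min"),
        common_metabolite_filter=CommonMetaboliteFilter(10, frozenset({hid})))
    outcome = od.apply_filters(env.pgdb, env.bundle, env.tree, cfg)
    for node in env.tree.base_nodes():
        before = len(node.member_row_keys())
        after = len(outcome.member_row_keys(node.uid))
        assert outcome.excluded_count(node.uid) == before - after


# -- conjunction / monotonicity ---------------------------------------------


def test_conjunction_equals_intersection_of_single_filters(env):
    vf = ValueFilter(80.0, "min")
    sf = SignificanceFilter(0.5, "max")
    both = od.apply_filters(env.pgdb, env.bundle, env.tree,
                            FilterConfig(value_filter=vf,
                                         significance_filter=sf))
    only_v = od.apply_filters(env.pgdb, env.bundle, env.tree,
                              FilterConfig(value_filter=vf))
    only_s = od.apply_filters(env.pgdb, env.bundle, env.tree,
                              FilterConfig(significance_filter=sf))
    assert both.included_rows == only_v.included_rows & only_s.included_rows
    for node in env.tree.walk():
        assert set(both.member_row_keys(node.uid)) == \
            set(only_v.member_row_keys(node.uid)) & \
            set(only_s.member_row_keys(node.uid))


@pytest.mark.parametrize("direction, tight, loose",
                         [("min", 100.0, 50.0), ("max", 50.0, 100.0)])
def test_loosening_threshold_is_monotone(env, direction, tight, loose):
    def included(t):
        cfg = FilterConfig(value_filter=ValueFilter(t, direction))
        return od.apply_filters(env.pgdb, env.bundle, env.tree,
                                cfg).included_rows
    assert included(tight) <= included(loose)


def test_hiding_a_column_can_only_shrink_inclusion(env):
    vf = ValueFilter(100.0, "min")
    full = od.apply_filters(env.pgdb, env.bundle, env.tree,
                            FilterConfig(value_filter=vf))
    visible = frozenset(env.bundle.display_order[:-2])
    part = od.apply_filters(env.pgdb, env.bundle, env.tree,
                            FilterConfig(value_filter=vf,
                                         visible_columns=visible))
    assert part.included_rows <= full.included_rows


def test_passing_row_keeps_all_its_columns(env):
    """Entity-level inclusion: a row passing in one column shows values in
    all visible columns of its plots."""
    vf = ValueFilter(120.0, "min")
    outcome = od.apply_filters(env.pgdb, env.bundle, env.tree,
                               FilterConfig(value_filter=vf))
    node = next(n for n in env.tree.base_nodes() if n.kind == "pathway"
                and set(outcome.member_row_keys(n.uid)))
    pdata = od.plot_data(node, env.bundle, outcome, env.axes)
    cols = {c.key: c for c in pdata.columns}
    for key in outcome.visible:
        for row in outcome.member_row_keys(node.uid):
            v = env.bundle.value(key, row[1]) if row[0] == key[0] else None
            if v is not None:
                assert (row, v) in cols[key].dots
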
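"""Axis constraints, aggregation, column styling, search, table export."""

import itertools

import numpy as np
import pytest

import omicsdash as od
from omicsdash.dashboard import (AxisConstraintError, DashboardError,
                                 PlotOptions, interleave_by_condition)

from conftest import make_metabolomics


def scale_bundle(scales):
    """Bundle of len(scales) one-column datasets with given value scales."""
    datatypes = ["metabolomics", "transcriptomics", "proteomics"]
    dss = []
    for i, s in enumerate(scales):
        dss.append(od.OmicsDataset(
            datatype=datatypes[i], value_scale=s,
            log_transformed=(s == "relative"),
            column_specs=[od.ColumnSpec(1, f"c{i}", "data")],
            rows=[("x", {1: 1.0})]))
    return od.OmicsBundle(datasets=dss)


def test_two_datasets_each_own_axis():
    for scales in itertools.product(("absolute", "relative"), repeat=2):
        axes = od.assign_axes(scale_bundle(list(scales)))
        assert sorted(axes.axis_of_dataset) == ["A", "B"]


def test_three_dataset_sharing_exhaustive():
    """All 8 scale combinations: returned assignments always satisfy the
    constraints; every user pairing is accepted iff compatible."""
    for scales in itertools.product(("absolute", "relative"), repeat=3):
        bundle = scale_bundle(list(scales))
        axes = od.assign_axes(bundle)
        # exactly two share
        assert sorted(axes.axis_of_dataset.count(a) for a in "AB") == [1, 2]
        for axis in "AB":
            shared = {scales[i] for i in axes.datasets_on(axis)}
            assert len(shared) == 1
        for pair in ((0, 1), (0, 2), (1, 2)):
            compatible = scales[pair[0]] == scales[pair[1]]
            if compatible:
                got = od.assign_axes(bundle, share_pair=pair)
                assert got.axis_of_dataset[pair[0]] == \
                    got.axis_of_dataset[pair[1]]
            else:
                with pytest.raises(AxisConstraintError):
                    od.assign_axes(bundle, share_pair=pair)


def test_mixed_scale_pairing_rejected_with_explanation():
    bundle = scale_bundle(["relative", "relative", "absolute"])
    with pytest.raises(AxisConstraintError, match="same type of data|same value scale"):
        od.assign_axes(bundle, share_pair=(1, 2))


def test_sides_are_user_selectable():
    bundle = scale_bundle(["absolute", "relative"])
    axes = od.assign_axes(bundle, sides={"A": "right", "B": "left"})
    assert axes.side_of_axis == {"A": "right", "B": "left"}
    with pytest.raises(AxisConstraintError):
        od.assign_axes(bundle, sides={"A": "left", "B": "left"})


def test_axis_labels_name_datatype_and_scale(env):
    assert "metabolomics" in env.axes.label_of_axis["A"]
    assert "log ratio" in env.axes.label_of_axis["B"]


# -- aggregation ------------------------------------------------------------


def test_singleton_mean_and_text(tca_pgdb):
    ds = make_metabolomics([("isocitrate", {1: 3.7})])
    bundle = od.OmicsBundle(datasets=[ds])
    tree = od.build_tree(tca_pgdb, bundle, od.DashboardConfig())
    outcome = od.apply_filters(tca_pgdb, bundle, tree, od.no_filters())
    axes = od.assign_axes(bundle)
    node = next(n for n in tree.base_nodes() if n.kind == "pathway")
    p = od.plot_data(node, bundle, outcome, axes)
    assert len(p.columns) == 1
    assert p.columns[0].dots == [((0, 0), 3.7)]
    assert p.columns[0].mean == 3.7
    assert p.mean_text is True


def test_mean_ignores_missing(tca_pgdb):
    ds = make_metabolomics([("isocitrate", {1: 2.0}), ("citrate", {1: 4.0}),
                            ("malate", {1: None})])
    bundle = od.OmicsBundle(datasets=[ds])
    tree = od.build_tree(tca_pgdb, bundle, od.DashboardConfig())
    outcome = od.apply_filters(tca_pgdb, bundle, tree, od.no_filters())
    node = next(n for n in tree.base_nodes() if n.kind == "pathway")
    p = od.plot_data(node, bundle, outcome, od.assign_axes(bundle))
    assert len(p.columns[0].dots) == 2
    assert p.columns[0].mean == 3.0


def test_mean_text_suppressed_with_multiple_columns(env):
    node = next(n for n in env.tree.base_nodes() if n.kind == "pathway")
    p = od.plot_data(node, env.bundle, env.outcome, env.axes)
    assert p.mean_text is False


def test_plot_means_match_table_oracle(env):
    """For every node and column the plotted mean equals the arithmetic
    mean of the exported table's values."""
    for node in env.tree.walk():
        p = od.plot_data(node, env.bundle, env.outcome, env.axes)
        df = od.export_table(node, env.bundle, env.outcome)
        for col in p.columns:
            series = df[env.bundle.legend_text(col.key)].dropna()
            assert len(series) == len(col.dots)
            assert col.mean == pytest.approx(series.mean())
        # columns absent from the plot have no table values either
        plotted = {c.key for c in p.columns}
        for key in env.outcome.visible:
            if key not in plotted:
                assert df[env.bundle.legend_text(key)].dropna().empty


def test_multiomics_plot_mixes_metabolite_and_gene_dots(env):
    node = next(n for n in env.tree.base_nodes()
                if n.kind == "pathway" and len(n.members) == 2)
    p = od.plot_data(node, env.bundle, env.outcome, env.axes)
    ds_of_cols = {c.key[0] for c in p.columns}
    assert ds_of_cols == {0, 1}
    for c in p.columns:
        for (d, _), _ in c.dots:
            assert d == c.key[0]


def test_y_range_contains_all_dots_and_means(env):
    for node in env.tree.walk():
        p = od.plot_data(node, env.bundle, env.outcome, env.axes)
        for col in p.columns:
            lo, hi = p.y_range[col.axis]
            for _, v in col.dots:
                assert lo <= v <= hi
            assert lo <= col.mean <= hi


def test_log_display_refused_for_log_ratio_data(env):
    node = next(n for n in env.tree.base_nodes() if n.kind == "pathway")
    with pytest.raises(DashboardError, match="log fold-change"):
        od.plot_data(node, env.bundle, env.outcome, env.axes,
                     PlotOptions(log_scale=True))


def test_log_display_transforms_absolute_data(tca_pgdb):
    ds = od.OmicsDataset(datatype="metabolomics", value_scale="absolute",
                         column_specs=[od.ColumnSpec(1, "v", "data")],
                         rows=[("isocitrate", {1: 100.0}),
                               ("citrate", {1: -5.0})])
    bundle = od.OmicsBundle(datasets=[ds])
    tree = od.build_tree(tca_pgdb, bundle, od.DashboardConfig())
    outcome = od.apply_filters(tca_pgdb, bundle, tree, od.no_filters())
    node = next(n for n in tree.base_nodes() if n.kind == "pathway")
    p = od.plot_data(node, bundle, outcome, od.assign_axes(bundle),
                     PlotOptions(log_scale=True))
    assert p.columns[0].dots == [((0, 0), 2.0)]  # log10(100)
    assert p.columns[0].n_log_omitted == 1       # the negative value


# -- column order and style -------------------------------------------------


def test_reorder_identity_and_inverse(env):
    order = list(env.bundle.display_order)
    same = od.reorder_columns(env.bundle, order)
    assert same.display_order == order
    perm = order[::-1]
    back = od.reorder_columns(od.reorder_columns(env.bundle, perm), order)
    assert back.display_order == order
    with pytest.raises(DashboardError, match="permutation"):
        od.reorder_columns(env.bundle, order[:-1])
    with pytest.raises(DashboardError, match="permutation"):
        od.reorder_columns(env.bundle, order[:-1] + [order[0]])


def test_interleave_by_condition_alternates_datasets(env):
    order = interleave_by_condition(env.bundle)
    assert sorted(order) == sorted(env.bundle.display_order)
    assert order[0][0] == 0 and order[1][0] == 1  # met then trn for cond 1


def test_restyle_updates_label_color_and_plots(env):
    key = env.bundle.display_order[0]
    restyled = od.restyle_column(env.bundle, key, label="T8", color="#000000")
    assert restyled.labels[key] == "T8"
    assert restyled.colors[key] == "#000000"
    node = next(n for n in env.tree.base_nodes() if n.kind == "pathway")
    p = od.plot_data(node, restyled, env.outcome, env.axes)
    col = next(c for c in p.columns if c.key == key)
    assert col.label == "T8" and col.color == "#000000"


# -- search -----------------------------------------------------------------


def test_search_returns_base_nodes_of_entity(env):
    node = next(n for n in env.tree.base_nodes() if n.kind == "pathway")
    ds_idx, rows = next(iter(env.outcome.members_of(node.uid).items()))
    name = env.bundle.datasets[ds_idx].entity_name(rows[0])
    hits = od.search(env.tree, env.outcome, env.bundle, name)
    assert node.uid in hits
    assert od.search(env.tree, env.outcome, env.bundle, "zzz-none") == []


def test_search_prefix_union(env):
    """A prefix matching several entities returns the union of their
    base nodes."""
    prefix = "cpd pwy 00"
    expect = set()
    for node in env.tree.base_nodes():
        for d, rows in env.outcome.members_of(node.uid).items():
            if any(env.bundle.datasets[d].entity_name(r)
                   .casefold().startswith(prefix) for r in rows):
                expect.add(node.uid)
    assert set(od.search(env.tree, env.outcome, env.bundle,
                         prefix.upper())) == expect
    assert expect


def test_search_respects_filters(env):
    """A hub excluded everywhere except its primary-io lineage is found
    only in those base pathways."""
    hid = env.manifest["hub_ids"][0]
    name = env.pgdb.compounds[hid].name
    cfg = od.FilterConfig(
        common_metabolite_filter=od.CommonMetaboliteFilter(
            10, frozenset({hid})))
    outcome = od.apply_filters(env.pgdb, env.bundle, env.tree, cfg)
    qual = {p.id for p in env.pgdb.pathways.values()
            if env.pgdb.compound_closure(hid) & p.primary_ids}
    hits = od.search(env.tree, outcome, env.bundle, name)
    for uid in hits:
        node = env.tree.get(uid)
        if node.kind == "pathway":
            assert node.pathway_ids & qual


def test_autocomplete_prefix_and_limit(env):
    sugg = od.autocomplete(env.bundle, "CPD", limit=5)
    assert 0 < len(sugg) <= 5
    assert all(s.casefold().startswith("cpd") for s in sugg)


# -- table ------------------------------------------------------------------


def test_table_rows_cover_all_datatypes(env):
    node = next(n for n in env.tree.base_nodes()
                if n.kind == "pathway" and len(n.members) == 2)
    df = od.export_table(node, env.bundle, env.outcome)
    assert set(df["datatype"]) == {"metabolomics", "transcriptomics"}
    n_members = len(env.outcome.member_row_keys(node.uid))
    assert len(df) == n_members


def test_table_sort_stable_missing_last(env):
    node = next(n for n in env.tree.base_nodes() if n.kind == "pathway")
    col = env.bundle.legend_text(env.outcome.visible[0])
    df = od.export_table(node, env.bundle, env.outcome, sort_by=col)
    vals = df[col].tolist()
    non_missing = [v for v in vals if v == v and v is not None]
    assert non_missing == sorted(non_missing)
    # missing values trail
    tail = vals[len(non_missing):]
    assert all(v is None or v != v for v in tail)
    with pytest.raises(DashboardError):
        od.export_table(node, env.bundle, env.outcome, sort_by="nope")
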
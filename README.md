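# omicsdash

Static, testable omics dashboards over pathway/genome databases.

`omicsdash` is for scientists who have a table of metabolomics,
transcriptomics or proteomics measurements — fold changes, intensities,
time courses — and want to see, at a glance, which cellular systems are
responding.  It maps each dataset row onto an organism database (compounds
with their chemical-class ontology, pathways with curated class
memberships and primary inputs/outputs, genes with GO and
transport/regulatory annotations), rolls the values up through a
system/subsystem hierarchy (Biosynthesis → Amino Acid Biosynthesis → one
pathway), filters them, and renders small-multiple panels: one X–Y plot
per subsystem, one vertical line per data column, a small dot per entity
value and a large circle at the column mean.

The computational core:

* **Class-closure matching.** A dataset that cannot distinguish
  stereoisomers may report *isocitrate* while a pathway lists
  *D-threo-isocitrate*.  Matching therefore expands every compound over
  the class DAG in both directions: a row naming a class reaches pathways
  listing its instances, and vice versa.  For compound *c* with closure
  *C(c)*, pathway membership is `{P : C(c) ∩ compounds(P) ≠ ∅}`.
* **Per-entity filtering.**  With a value filter (threshold *t*,
  direction, optional |·|) and a significance filter (per data column a
  mapped significance column, e.g. a *p*-value maximum), an entity is
  included iff **some visible column** passes **every** configured
  filter; once included, all of its columns are displayed, so averages
  stay comparable across timepoints.
* **Common-metabolite exclusion.**  Hub compounds (≥ 10 pathways by
  default — ATP-like species) can be excluded, but remain shown in any
  pathway for which a curator designated them a primary input or output,
  and in every system containing such a pathway.
* **Multi-omics axes.**  Up to three component datasets plot side by
  side with two Y-axes; with three datasets exactly two share an axis,
  and datasets sharing an axis must have the same value scale (log
  fold-change vs absolute quantities).

Everything is a pure function of its inputs: rendering the same database
and dataset twice yields byte-identical SVG/HTML/JSON.

## Worked example

The built-in generator creates a synthetic organism database and matching
datasets (six metabolomics timepoints plus two transcriptomics log-ratio
columns), so the whole pipeline runs without any downloads:

```python
import omicsdash as od

fx, fd = od.make_fixture(seed=1)                      # PGDB + datasets
tree = od.build_tree(fx.pgdb, fd.bundle, fx.config)   # pruned hierarchy
outcome = od.apply_filters(fx.pgdb, fd.bundle, tree, od.no_filters())
axes = od.assign_axes(fd.bundle)

print([p.name for p in tree.panels])
node = tree.get("Other-Pathways/Other-Pathways-sub1/Other-Pathways-sub1-deep/pwy-031")
for c in od.plot_data(node, fd.bundle, outcome, axes).columns[:3]:
    print(f"{c.legend}: {len(c.dots)} dots, mean {c.mean:.2f} (axis {c.axis})")
```

prints

```
['Biosynthesis', 'Degradation', 'Energy Metabolism', 'Other Pathways',
 'Central Dogma', 'Response to Stimulus', 'Cell Exterior']
metabolomics: t8h: 6 dots, mean 60.16 (axis A)
metabolomics: t16h: 6 dots, mean 63.95 (axis A)
metabolomics: t24h: 6 dots, mean 53.98 (axis A)
```

Seven panels survive pruning: the four pathway-class panels plus three
non-metabolic panels (GO-term groups and transporter/regulator
subsystems) fed by the transcriptomics component.  The chosen base
pathway has six metabolite members and one gene member; metabolite
columns use the left axis (absolute abundances), transcriptomics columns
the right (log ratios).  Asking for the hub-metabolite checklist and
excluding one hub,

```python
cfg = od.FilterConfig(common_metabolite_filter=od.CommonMetaboliteFilter(
    10, frozenset({"hub-1"})))
outcome = od.apply_filters(fx.pgdb, fd.bundle, tree, cfg)
print(outcome.candidates)
```

prints `[('hub-1', 12), ('hub-2', 12), ('hub-3', 12)]` — three compounds
participate in twelve pathways each — and `hub-1` disappears from every
plot except the pathway that names it a primary output (and that
pathway's ancestors), with per-panel "1 excluded" messages elsewhere.

Rendering writes an `index.html` with a global legend plus one SVG per
subsystem:

```python
files = od.render_dashboard(tree, fd.bundle, outcome, axes, pgdb=fx.pgdb)
od.write_render(files, "scratch/dashboard")
```

The same pipeline is scriptable from a shell via the `omicsdash` CLI
(`omicsdash fixtures`, `validate-pgdb`, `parse`, `average`, `map`,
`tree`, `render`, `table`, `search`, `overlay`).

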
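# Methods

## Data model

The organism database ("PGDB") is a single versioned JSON document
(`src/omicsdash/data/pgdb.schema.json`) holding five collections:

* **compounds** — chemical species in a class DAG.  A *class* node (e.g.
  "isocitrate") groups *instance* nodes (its stereoisomers); instances
  may have class parents and classes may have class parents.  Names and
  synonyms are indexed case-folded with whitespace collapsed.
* **pathway classes** — a DAG of pathway categories with four designated
  parentless roots (`Biosynthesis`, `Degradation`, `Energy-Metabolism`,
  `Other-Pathways`) that become the metabolic dashboard panels.
* **pathways** — participant compounds (instances or classes), enzyme
  genes, one or more pathway classes, and curator-designated primary
  input/output compounds.
* **GO terms** — a DAG; genes annotate to terms, and term-based
  subsystems include genes annotated to the term *or any descendant*.
* **genes** — names, synonyms, optional product name, GO annotations,
  and activity tags (`transporter`, `regulator`) used for computed
  subsystems.

Loading validates field types, rejects dangling references and DAG
cycles (topological check via networkx), and reports error locations as
JSON-pointer paths.  All derived indexes are rebuilt on load, so two
loads of one file produce identical structures.

## Class-closure matching

The closure of compound *c* is *c* plus all descendants plus all
ancestors in the class DAG.  The descending direction implements the
standard ontology semantics (a class covers its instances).  The
ascending direction is this package's deliberate extension: a dataset row
naming an *instance* must also reach pathways that list the *class*,
otherwise matching would depend on which level the data provider and the
curator happened to choose.  Symmetry makes matching independent of that
choice; its cost is that a row naming a specific isomer also matches
pathways of sibling isomers through the shared class, which we consider
the right trade-off for data that usually cannot distinguish them anyway.

A compound's pathway set is every pathway whose participant list
intersects the closure; a compound's *pathway count* (used by the
common-metabolite filter) is the size of that set.

## Entity resolution

Metabolomics rows resolve against compounds; transcriptomics, proteomics
and flux rows against genes (proteins via their genes' names, synonyms
and product names; flux data via the enzymes that carry it).  Precedence
is exact id, then case-folded name, then synonym.  All matches at the
winning level are retained: an ambiguous row contributes to the union of
its matches' memberships but is counted at most once per plot.
Unmatched rows are kept with `match_kind = "none"` and surface in the
"objects not present in any subsystem" panel together with matched
entities that sit in no pathway and carry no dashboard-relevant
annotation.  By construction, the node-membership union and the unmapped
set partition the dataset rows.

## Dashboard hierarchy

The four metabolic panels mirror a *curated* view of the pathway-class
taxonomy, not the raw taxonomy: a YAML configuration lists, per parent
class, the child classes shown explicitly (in order); unlisted siblings'
pathways merge into one "Other *parent*" bucket per parent; classes more
than `flatten_depth` levels below a panel root (default 3) are flattened
to direct pathway leaves.  Parents without a curation entry show all
children alphabetically — the shipped default, since real curations are
database-specific.  Base subsystems are individual pathways, so the base
set is invariant to the flatten depth.  Non-metabolic panels (Central
Dogma, Response to Stimulus, Cellular Processes, Virulence-Related, Cell
Exterior) are built from configured GO-term groups plus activity-tag
subsystems, and only when the bundle carries gene-resolving data —
metabolomics data cannot be displayed on them.  Every node stores its
pre-filter members (own rule ∪ children's members, which keeps
mixed-rule containers monotone under tree containment); nodes with zero
members are pruned, making panels both organism- and dataset-dependent.
Node identity is the slash-joined path from the panel root, so a pathway
under two classes yields two distinct tree nodes and drill-down paths
stay unique.  Custom top-level panels accept any mix of pathway, class,
GO-term, gene and compound ids and reuse the same membership rules.
Plot labels default to first-letter initials of the subsystem name, with
configurable overrides.

## Filtering

Filters act per entity over the *visible* data columns; configured
filters combine by conjunction; comparisons are inclusive (≥/≤, matching
the "ten or more" convention of the common-metabolite threshold).

* **Value filter** — passes if some visible column of the row's dataset
  has a non-missing value (optionally |value|) meeting the min/max
  threshold.
* **Significance filter** — passes if some visible data column *with a
  mapped significance column* meets the threshold (a maximum for
  p-values); unmapped columns are never considered, and a missing
  significance value cannot pass (failing, not exempt — the conservative
  reading).
* **Common-metabolite filter** — metabolomics only.  The candidate
  checklist (pathway count ≥ threshold, default 10) is advisory; only
  user-selected ids are excluded.  An excluded compound is removed from
  every node except those containing a pathway whose primary
  inputs/outputs intersect the compound's closure — i.e. the qualifying
  pathway and all its ancestors, including "Other" buckets (the
  exemption propagates wherever the pathway does).

A row that passes shows **all** its visible columns, including
individually failing ones, so per-subsystem averages compare like with
like across columns.  Per-node exclusion lists record each removed row
and the reason; for base panels the exclusion count equals the
member-count difference and renders as an "n excluded" message with the
entity names in a tooltip.

## Aggregation and axes

Plot dots are the filtered members' non-missing values per column;
the column mean is arithmetic over those dots (missing values are
ignored rather than imputed).  Columns with no values are omitted from
the plot.  The mean is printed as text only when exactly one data column
is visible.  The optional log10 display transform applies to absolute
data only — it is refused for log-ratio data, which is already
logarithmic — and non-positive values are omitted from log plots with a
per-plot count.  Panel Y-ranges default to the data range padded 5%, per
axis, overridable.

Axis assignment: one axis for a single dataset; two datasets get one
axis each; with three, exactly two share an axis and every axis must be
scale-homogeneous (relative with relative, absolute with absolute).  A
requested pairing violating this is rejected; otherwise the user's
choice of pairing and of left/right sides is honored, defaulting to the
first valid pairing in dataset order.

## File formats

Single-omics files are tab-delimited: column 0 entity names, declared
columns are data, significance (each tied to one data column) or
ignored.  A header row is auto-detected (a non-numeric, non-missing
token in a declared data column).  Missing cells are "", "NA", "NaN"
(case-insensitive); any other non-numeric token becomes missing plus a
warning — rows are never silently dropped, and duplicate entity names
are kept with a warning, treated downstream as distinct rows attached to
the same entity.  Numeric parsing accepts a decimal point only.  The
combined multi-omics dialect prefixes each of 2–3 blocks with `#!
key=value` metadata lines (`dataset`, `value_scale`, `log_transformed`,
`data_cols`, `sig_cols`); the key set is this package's own dialect,
designed so that `parse ∘ write` is the identity on the data model.
Replicate averaging (arithmetic mean per group, ignoring missing;
all-missing groups stay missing) applies to stand-alone datasets only
and is refused inside multi-omics bundles, which must arrive
pre-averaged; log data are averaged as given.

## Rendering and overlays

SVG/HTML output is built by deterministic string construction: no
timestamps, stable float formatting, stable iteration orders — identical
inputs give identical bytes, which the test suite exploits.  Base-panel
views draw one plot per member entity.  Pathway-diagram layout is out of
scope; `overlay_export` instead emits per-entity, per-column values and
colors for external diagram tools, with one independent scale per
datatype: linear binning (default 9 bins) over the datatype's global
value range, a zero-centered symmetric range with a diverging
blue–white–red palette for relative data and a sequential palette for
absolute data.

## Synthetic data generator

`fixtures` builds a structurally complete miniature database: four
metabolic roots each with two curated child classes (one nesting a
deeper class to exercise flattening), an uncurated sibling (exercising
"Other" buckets), three pathways per class plus one attached directly at
a curated class; per-pathway instance compounds plus, on the deep
classes, a class-compound chain with two instance "isomers" of which
only one participates (the stereoisomer-matching scenario); hub
compounds placed in 12 pathways each (above the common-metabolite
threshold of 10) and designated a primary output of their first host;
enzyme genes, GO groups with child-term-only annotations (exercising
rollup), transporter/regulator genes, and orphan objects that resolve
but map nowhere.  Structure is seed-independent; only sampled values and
name draws vary, and all randomness flows from a single
`numpy.random.default_rng(seed)`.

Datasets mirror common study shapes: a single treatment-vs-control log
fold-change file with a p-value column; a combined file with six
metabolomics timepoints (absolute abundances, log-normal around e⁴) and
two transcriptomics log-ratio columns with significance columns; and a
2-condition × 3-replicate file.  Rows in one designated "responsive"
pathway draw relative values from Normal(3, 1) versus Normal(0, 1)
elsewhere; 10% of rows get unknown names, 5% of cells are missing.  A
brute-force manifest (BFS closures and linear scans over the raw
dictionaries, independent of the indexed implementation) records every
constructed truth the tests assert against.

What the generator does **not** emulate: real nomenclature ambiguity
beyond synonyms, identifier cross-references (ChEBI/HMDB), batch
effects, correlated replicates, or realistic pathway topology.  Passing
tests therefore demonstrate the correctness of the mapping, filtering
and aggregation *logic*, not identification accuracy on real datasets.

## Problem sizes and numerics

The default fixture is 40 pathways / ~170 compounds / ~90 genes with a
100-row bundle; oracle sweeps use 50 random DAGs of up to 200 nodes and
100 random filter configurations — sizes chosen so the full verification
pipeline completes in seconds while still exercising every code path.
Ties in curated child ordering break alphabetically; table sorts are
stable with missing values last; closure and membership computations are
exact set operations, so the only floating-point comparisons in the
tests are means (compared with `pytest.approx`) and the acceptance
script's `aggregation_max_abs_mean_error`, which is exactly 0.0 because
plot means and table means share the same IEEE additions.

## Known limitations

* No fuzzy name matching or identifier translation; resolution is
  exact-string (case-folded) over ids, names and synonyms.
* The significance filter assumes significance columns live in the same
  dataset as the data columns they govern.
* The log-scale display option is all-or-nothing per plot rather than
  per axis.
* `exclude_nodes` removes nodes after membership computation, so
  ancestors of an excluded plot retain its rows (the excluded pathway's
  data remains part of the containing system's aggregate).
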
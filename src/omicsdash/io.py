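"""Reading and writing omics data files.

Two dialects are supported:

* **single-omics**: a tab-delimited text file whose first column holds
  metabolite / gene / protein names or identifiers and whose remaining
  columns hold data values, optional significance values (p-values,
  signal-to-noise ratios) or ignored content.  A header row is
  auto-detected.

* **combined multi-omics**: two or three single-omics blocks in one file,
  each preceded by ``#!`` metadata lines declaring datatype, value scale
  and column roles, blocks separated by blank lines.

Values may be *absolute* (counts, intensities) or *relative* (ratios or
log ratios, flagged ``log_transformed``).  Missing cells are the empty
string, ``NA`` or ``NaN`` (case-insensitive); any other non-numeric token
in a data column is treated as missing and counted as a warning — no row
is ever silently dropped.

Replicate averaging (arithmetic mean per group of data columns, ignoring
missing values) is provided for stand-alone datasets only; it is refused
for components of a multi-omics bundle, where each component must arrive
pre-averaged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

DATATYPES = ("metabolomics", "transcriptomics", "proteomics", "flux")
VALUE_SCALES = ("absolute", "relative")
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: datatypes whose rows resolve against the gene namespace
GENE_DATATYPES = frozenset({"transcriptomics", "proteomics", "flux"})


class OmicsIOError(Exception):
    pass


@dataclass(frozen=True)
class ColumnSpec:
    """Role of one file column (0-based index; column 0 is always names)."""

    index: int
    label: str
    role: str  # "data" | "significance" | "ignored"
    significance_for: int | None = None

    def __post_init__(self):
        if self.role not in ("data", "significance", "ignored"):
            raise OmicsIOError(f"bad column role {self.role!r}")
        if self.significance_for is not None and self.role != "significance":
            raise OmicsIOError("significance_for only valid on significance columns")


@dataclass
class OmicsDataset:
    """One datatype's entity-by-column matrix.

    ``rows`` is an ordered list of ``(entity_name, values)`` pairs where
    ``values`` maps a declared column index to a float or ``None``
    (missing).  ``bundle_member`` is set when the dataset is placed inside
    an :class:`OmicsBundle`.
    """

    datatype: str
    value_scale: str
    column_specs: list[ColumnSpec]
    rows: list[tuple[str, dict[int, float | None]]]
    log_transformed: bool = False
    warnings: list[str] = field(default_factory=list)
    n_bad_cells: int = 0
    bundle_member: bool = False

    def __post_init__(self):
        if self.datatype not in DATATYPES:
            raise OmicsIOError(f"unknown datatype {self.datatype!r}")
        if self.value_scale not in VALUE_SCALES:
            raise OmicsIOError(f"unknown value_scale {self.value_scale!r}")
        if not self.data_columns:
            raise OmicsIOError("dataset declares no data columns")
        by_index = {c.index: c for c in self.column_specs}
        for c in self.column_specs:
            if c.significance_for is not None:
                target = by_index.get(c.significance_for)
                if target is None or target.role != "data":
                    raise OmicsIOError(
                        f"significance column {c.index} references non-data column"
                        f" {c.significance_for}")

    @property
    def data_columns(self) -> list[ColumnSpec]:
        return [c for c in self.column_specs if c.role == "data"]

    @property
    def significance_columns(self) -> list[ColumnSpec]:
        return [c for c in self.column_specs if c.role == "significance"]

    def significance_map(self) -> dict[int, int]:
        """data column index -> its declared significance column index."""
        return {c.significance_for: c.index for c in self.significance_columns
                if c.significance_for is not None}

    def value(self, row_idx: int, col_idx: int) -> float | None:
        return self.rows[row_idx][1].get(col_idx)

    def entity_name(self, row_idx: int) -> str:
        return self.rows[row_idx][0]

    @property
    def is_log_relative(self) -> bool:
        return self.value_scale == "relative" and self.log_transformed


@dataclass
class OmicsBundle:
    """1-3 datasets displayed together.

    Display columns are ``(dataset_index, column_index)`` keys; default
    order is dataset-major (all columns of dataset 1, then 2, then 3).
    """

    datasets: list[OmicsDataset]
    display_order: list[tuple[int, int]] = field(default_factory=list)
    labels: dict[tuple[int, int], str] = field(default_factory=dict)
    colors: dict[tuple[int, int], str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= len(self.datasets) <= 3:
            raise OmicsIOError(
                f"a bundle holds 1-3 datasets, got {len(self.datasets)}")
        for ds in self.datasets:
            ds.bundle_member = len(self.datasets) > 1
        default = [(i, c.index) for i, ds in enumerate(self.datasets)
                   for c in ds.data_columns]
        if not self.display_order:
            self.display_order = default
        if set(self.display_order) != set(default) or \
                len(self.display_order) != len(default):
            raise OmicsIOError("display_order is not a permutation of data columns")
        for key in self.display_order:
            self.labels.setdefault(key, self._colspec(key).label)
        seen = {}
        for i, ds in enumerate(self.datasets):
            if ds.datatype in seen:
                self.warnings.append(
                    f"duplicate datatype {ds.datatype!r} (datasets"
                    f" {seen[ds.datatype]} and {i})")
            else:
                seen[ds.datatype] = i

    def _colspec(self, key: tuple[int, int]) -> ColumnSpec:
        ds_idx, col_idx = key
        for c in self.datasets[ds_idx].column_specs:
            if c.index == col_idx:
                return c
        raise OmicsIOError(f"no such column {key}")

    def value(self, key: tuple[int, int], row_idx: int) -> float | None:
        return self.datasets[key[0]].value(row_idx, key[1])

    def datatype_of(self, key: tuple[int, int]) -> str:
        return self.datasets[key[0]].datatype

    def legend_text(self, key: tuple[int, int]) -> str:
        return f"{self.datatype_of(key)}: {self.labels[key]}"

    def all_row_keys(self) -> list[tuple[int, int]]:
        return [(i, r) for i, ds in enumerate(self.datasets)
                for r in range(len(ds.rows))]

    @property
    def has_metabolomics(self) -> bool:
        return any(ds.datatype == "metabolomics" for ds in self.datasets)

    @property
    def has_gene_data(self) -> bool:
        return any(ds.datatype in GENE_DATATYPES for ds in self.datasets)


# ---------------------------------------------------------------------------
# parsing


def _try_float(token: str) -> float | None:
    try:
        return float(token)
    except ValueError:
        return None


def _is_missing(token: str) -> bool:
    return token.strip().casefold() in MISSING_TOKENS


def parse_single_omics(path: str | os.PathLike, datatype: str, value_scale: str,
                       column_specs: list[ColumnSpec],
                       log_transformed: bool = False) -> OmicsDataset:
    """Parse a tab-delimited single-omics file.

    The first physical row is taken as a header when at least one declared
    data column holds a token that is neither numeric nor a missing token.
    Header labels override the labels in ``column_specs``.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as e:
        raise OmicsIOError(f"cannot read {path}: {e}") from e
    table = [line.split("\t") for line in lines if line.strip() != ""]
    return _parse_block(table, datatype, value_scale, column_specs, log_transformed)


def _parse_block(table: list[list[str]], datatype: str, value_scale: str,
                 column_specs: list[ColumnSpec],
                 log_transformed: bool) -> OmicsDataset:
    specs = sorted(column_specs, key=lambda c: c.index)
    data_idx = [c.index for c in specs if c.role == "data"]
    if not data_idx:
        raise OmicsIOError("no data columns declared")
    declared = [c.index for c in specs]

    warnings: list[str] = []
    n_bad = 0

    def cell(row: list[str], idx: int) -> str:
        return row[idx] if idx < len(row) else ""

    header = None
    if table:
        first = table[0]
        if any(not _is_missing(cell(first, i)) and _try_float(cell(first, i)) is None
               for i in data_idx):
            header = first
            table = table[1:]
    if header is not None:
        specs = [replace(c, label=cell(header, c.index).strip() or c.label)
                 for c in specs]

    rows: list[tuple[str, dict[int, float | None]]] = []
    seen_names: set[str] = set()
    for row in table:
        name = cell(row, 0).strip()
        if name in seen_names:
            warnings.append(f"duplicate entity name {name!r}; keeping both rows")
        seen_names.add(name)
        values: dict[int, float | None] = {}
        for idx in declared:
            tok = cell(row, idx)
            if _is_missing(tok):
                values[idx] = None
            else:
                v = _try_float(tok)
                if v is None:
                    values[idx] = None
                    n_bad += 1
                    warnings.append(
                        f"non-numeric value {tok!r} for {name!r} in column {idx};"
                        " treated as missing")
                else:
                    values[idx] = v
        rows.append((name, values))

    return OmicsDataset(datatype=datatype, value_scale=value_scale,
                        column_specs=specs, rows=rows,
                        log_transformed=log_transformed,
                        warnings=warnings, n_bad_cells=n_bad)


# combined multi-omics dialect -----------------------------------------------
#
#   #! dataset=metabolomics
#   #! value_scale=absolute
#   #! log_transformed=false
#   #! data_cols=1,2,3
#   #! sig_cols=4:1
#   name<TAB>t8<TAB>...
#   ...rows...
#   <blank line>
#   #! dataset=transcriptomics
#   ...
#
# ``sig_cols`` entries are significance_column:data_column index pairs.


def parse_combined_multiomics(path: str | os.PathLike) -> OmicsBundle:
    """Parse a combined multi-omics file into a bundle of 2-3 datasets."""
    try:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as e:
        raise OmicsIOError(f"cannot read {path}: {e}") from e

    blocks: list[tuple[dict[str, str], list[list[str]]]] = []
    meta: dict[str, str] = {}
    body: list[list[str]] = []
    in_body = False
    for line in lines:
        if line.startswith("#!"):
            if in_body and meta:
                blocks.append((meta, body))
                meta, body, in_body = {}, [], False
            entry = line[2:].strip()
            if "=" not in entry:
                raise OmicsIOError(f"malformed metadata line {line!r}")
            key, _, value = entry.partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip() == "":
            continue
        else:
            in_body = True
            body.append(line.split("\t"))
    if meta or body:
        blocks.append((meta, body))

    if len(blocks) > 3:
        raise OmicsIOError(f"at most 3 datasets per combined file, got {len(blocks)}")
    if len(blocks) < 2:
        raise OmicsIOError("a combined multi-omics file needs at least 2 datasets")

    datasets = []
    for bi, (m, tbl) in enumerate(blocks):
        for req in ("dataset", "value_scale", "data_cols"):
            if req not in m:
                raise OmicsIOError(f"block {bi}: metadata missing {req!r}")
        specs = [ColumnSpec(index=int(t), label=f"col{t}", role="data")
                 for t in m["data_cols"].split(",") if t.strip()]
        for pair in m.get("sig_cols", "").split(","):
            if pair.strip():
                s, _, d = pair.partition(":")
                specs.append(ColumnSpec(index=int(s), label=f"col{s}",
                                        role="significance",
                                        significance_for=int(d)))
        datasets.append(_parse_block(
            tbl, m["dataset"], m["value_scale"], specs,
            m.get("log_transformed", "false").casefold() == "true"))
    return OmicsBundle(datasets=datasets)


# ---------------------------------------------------------------------------
# writing


def _format_value(v: float | None) -> str:
    if v is None:
        return ""
    return repr(v)


def _dataset_lines(ds: OmicsDataset) -> list[str]:
    specs = sorted(ds.column_specs, key=lambda c: c.index)
    width = max(c.index for c in specs) + 1
    header = ["name"] + [""] * (width - 1)
    for c in specs:
        header[c.index] = c.label
    out = ["\t".join(header)]
    for name, values in ds.rows:
        cells = [name] + [""] * (width - 1)
        for c in specs:
            cells[c.index] = _format_value(values.get(c.index))
        out.append("\t".join(cells))
    return out


def write_dataset(dataset: OmicsDataset, path: str | os.PathLike) -> None:
    """Write a single-omics TSV (header + rows) in the dialect parse reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(_dataset_lines(dataset)) + "\n")


def write_bundle(bundle: OmicsBundle, path: str | os.PathLike) -> None:
    """Write a combined multi-omics file with full ``#!`` metadata."""
    parts = []
    for ds in bundle.datasets:
        meta = [
            f"#! dataset={ds.datatype}",
            f"#! value_scale={ds.value_scale}",
            f"#! log_transformed={'true' if ds.log_transformed else 'false'}",
            "#! data_cols=" + ",".join(str(c.index) for c in ds.data_columns),
        ]
        sig = ",".join(f"{c.index}:{c.significance_for}"
                       for c in ds.significance_columns)
        if sig:
            meta.append(f"#! sig_cols={sig}")
        parts.append("\n".join(meta + _dataset_lines(ds)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# replicate averaging


def average_replicates(dataset: OmicsDataset,
                       groups: list[list[int]],
                       labels: list[str] | None = None) -> OmicsDataset:
    """Average groups of replicate data columns (arithmetic mean).

    Each group is a list of data-column indices; groups must be disjoint.
    Missing values are ignored; a group with no observed value yields a
    missing cell.  Refused for datasets inside a multi-omics bundle, where
    replicates must be averaged before upload.
    """
    if dataset.bundle_member:
        raise OmicsIOError(
            "replicate averaging is not supported in multi-omics mode; average"
            " replicates before combining datasets")
    data_idx = {c.index for c in dataset.data_columns}
    flat: list[int] = []
    for g in groups:
        if not g:
            raise OmicsIOError("empty replicate group")
        flat.extend(g)
    if len(set(flat)) != len(flat):
        raise OmicsIOError("replicate groups overlap")
    unknown = set(flat) - data_idx
    if unknown:
        raise OmicsIOError(f"not data columns: {sorted(unknown)}")

    if labels is None:
        by_index = {c.index: c.label for c in dataset.column_specs}
        labels = ["|".join(by_index[i] for i in g) for g in groups]
    specs = [ColumnSpec(index=k + 1, label=labels[k], role="data")
             for k in range(len(groups))]
    rows = []
    for name, values in dataset.rows:
        out: dict[int, float | None] = {}
        for k, g in enumerate(groups):
            obs = [values[i] for i in g if values.get(i) is not None]
            out[k + 1] = sum(obs) / len(obs) if obs else None
        rows.append((name, out))
    return OmicsDataset(datatype=dataset.datatype, value_scale=dataset.value_scale,
                        column_specs=specs, rows=rows,
                        log_transformed=dataset.log_transformed)
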
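"""Readers and writers for the plain-text tables the pipeline exchanges.

Every table is tab-separated UTF-8 without quoting.  Expression matrices
are genes x arrays with array IDs in the header row and gene IDs in the
first column; detection-flag tables share the same shape with 0/1 cells.
Missing values are not part of the data model: the only missingness
mechanism in this analysis is the detection-flag filter, so an ``NA`` cell
is a format error, not a value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the documented table contract."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

#: Column order for the array-design table.
DESIGN_COLUMNS = ("array", "group", "subgroup")

QPCR_COLUMNS = ("individual", "group", "gene", "replicate", "ct")

MORPHOMETRY_COLUMNS = (
    "placenta",
    "group",
    "field",
    "capillaries",
    "villi",
    "cd45",
    "cd3",
    "cd19",
)


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix plus optional detection flags and array design.

    Parameters
    ----------
    values
        genes x arrays DataFrame of log2 intensities (index = gene IDs,
        columns = array IDs, both unique).
    flags
        Optional boolean DataFrame of per-gene, per-array "detected" calls,
        aligned with ``values``.
    design
        Optional DataFrame indexed by array ID with columns ``group`` and
        ``subgroup`` mapping every array to its experimental group.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None
    design: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate array ID {dup!r}")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise FormatError(
                    f"flags shape {self.flags.shape} != values shape {self.values.shape}"
                )
            if not (
                self.flags.index.equals(self.values.index)
                and self.flags.columns.equals(self.values.columns)
            ):
                raise FormatError("flags index/columns do not match values")
        if self.design is not None:
            missing = [a for a in self.values.columns if a not in self.design.index]
            if missing:
                raise FormatError(f"arrays missing from design: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def groups(self) -> dict[str, list[str]]:
        """Arrays per group, in array order, from the attached design."""
        if self.design is None:
            raise FormatError("no design attached")
        out: dict[str, list[str]] = {}
        for array in self.array_ids:
            out.setdefault(str(self.design.loc[array, "group"]), []).append(array)
        return out

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in current matrix order)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(
            values=self.values.loc[keep],
            flags=None if self.flags is None else self.flags.loc[keep],
            design=self.design,
        )


@dataclass
class EdgeList:
    """Undirected gene-interaction edges stored canonically (a < b).

    ``n_self_loops_dropped`` counts self-loop rows rejected on read.
    """

    edges: list[tuple[str, str]] = field(default_factory=list)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    n_self_loops_dropped: int = 0

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-loop edge ({a},{b}) in EdgeList")
            e = (a, b) if a < b else (b, a)
            if e not in seen:
                seen.add(e)
                canon.append(e)
        self.edges = canon
        self.weights = {
            ((a, b) if a < b else (b, a)): w for (a, b), w in self.weights.items()
        }

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Expression / flag matrices
# ---------------------------------------------------------------------------


def _parse_matrix(path: str | Path, cast):
    """Parse a header+first-column TSV matrix, reporting 1-based line numbers."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: line 1: header must list at least one array ID")
    array_ids = header[1:]
    if len(set(array_ids)) != len(array_ids):
        dup = next(a for a in array_ids if array_ids.count(a) > 1)
        raise FormatError(f"{path}: line 1: duplicate array ID {dup!r}")
    genes: list[str] = []
    seen: set[str] = set()
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        gene = cells[0]
        if gene in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate gene ID {gene!r}")
        seen.add(gene)
        row = []
        for col, cell in zip(array_ids, cells[1:]):
            try:
                value = cast(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric cell {cell!r} in array {col!r}"
                ) from None
            if isinstance(value, float) and not np.isfinite(value):
                raise FormatError(
                    f"{path}: line {lineno}: non-finite cell {cell!r} in array {col!r}"
                )
            row.append(value)
        genes.append(gene)
        rows.append(row)
    return genes, array_ids, rows


def read_expression(path: str | Path, design: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes x arrays log2-intensity TSV.

    Ragged rows, non-numeric or ``NA`` cells and duplicate IDs are rejected
    with the offending line number.
    """
    genes, arrays, rows = _parse_matrix(path, float)
    values = pd.DataFrame(rows, index=genes, columns=arrays, dtype=float)
    return ExpressionMatrix(values=values, design=design)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    _write_matrix(matrix.values, path, fmt=lambda v: repr(float(v)))


def read_flags(path: str | Path) -> pd.DataFrame:
    """Read a 0/1 detection-flag TSV into a boolean DataFrame."""

    def cast(cell: str) -> int:
        v = int(cell)
        if v not in (0, 1):
            raise ValueError(cell)
        return v

    genes, arrays, rows = _parse_matrix(path, cast)
    return pd.DataFrame(rows, index=genes, columns=arrays, dtype=bool)


def write_flags(flags: pd.DataFrame, path: str | Path) -> None:
    _write_matrix(flags.astype(int), path, fmt=str)


def _write_matrix(df: pd.DataFrame, path: str | Path, fmt) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Design, annotation, edges
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design table missing columns {missing}")
    if df["array"].duplicated().any():
        dup = df.loc[df["array"].duplicated(), "array"].iloc[0]
        raise FormatError(f"{path}: duplicate array {dup!r} in design")
    return df.set_index("array")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index(names="array").to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene→term TSV; identical (gene, term) rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        return pd.DataFrame(columns=["gene", "term"])
    if not {"gene", "term"}.issubset(df.columns):
        raise FormatError(f"{path}: annotation table needs 'gene' and 'term' columns")
    return df[["gene", "term"]].drop_duplicates(ignore_index=True)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[["gene", "term"]].to_csv(path, sep="\t", index=False)


def term_to_genes(annotation: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, term in annotation[["gene", "term"]].itertuples(index=False):
        out.setdefault(term, set()).add(gene)
    return out


def read_edges(path: str | Path) -> EdgeList:
    """Read a 2/3-column edge TSV (gene1, gene2[, weight]).

    Self-loops are dropped and counted; (a,b)/(b,a) duplicates collapse to
    one canonical edge.  An empty file yields an empty EdgeList.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    start = 0
    if lines and lines[0].split("\t")[0] in ("gene1", "source"):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split("\t")
        if len(cells) < 2:
            raise FormatError(f"{path}: line {lineno}: expected at least 2 columns")
        a, b = cells[0], cells[1]
        if a == b:
            n_self += 1
            continue
        e = (a, b) if a < b else (b, a)
        edges.append(e)
        if len(cells) >= 3:
            try:
                weights[e] = float(cells[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric weight {cells[2]!r}"
                ) from None
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop edge(s)", stacklevel=2)
    return EdgeList(edges=edges, weights=weights, n_self_loops_dropped=n_self)


def write_edges(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tweight\n" if edge_list.weights else "gene1\tgene2\n")
        for a, b in edge_list.edges:
            if edge_list.weights:
                fh.write(f"{a}\t{b}\t{edge_list.weights.get((a, b), 1.0)!r}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# qPCR / morphometry / truth
# ---------------------------------------------------------------------------


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: qPCR table missing columns {missing}")
    if (df["ct"] <= 0).any():
        raise FormatError(f"{path}: Ct values must be positive")
    return df[list(QPCR_COLUMNS)]


def write_qpcr(df: pd.DataFrame, path: str | Path) -> None:
    df[list(QPCR_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_morphometry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: morphometry table missing columns {missing}")
    counts = df[list(MORPHOMETRY_COLUMNS[3:])]
    if (counts < 0).any().any() or not all(
        np.issubdtype(t, np.integer) for t in counts.dtypes
    ):
        raise FormatError(f"{path}: counts must be non-negative integers")
    return df[list(MORPHOMETRY_COLUMNS)]


def write_morphometry(df: pd.DataFrame, path: str | Path) -> None:
    df[list(MORPHOMETRY_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
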
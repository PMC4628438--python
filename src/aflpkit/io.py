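"""Readers and writers for the pipeline's external formats.

Formats covered: fragment-intensity CSV (the shape of a GeneMapper peak
export: one row per isolate x replicate x plate x locus), binary scoring
matrix TSV, isolate metadata CSV, PHYLIP square distance matrices, and
Newick trees whose internal node labels carry bootstrap support.

Readers validate and report offending line numbers; they never silently
drop rows.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .cluster import TreeNode
from .containers import INTENSITY_COLUMNS, METADATA_COLUMNS, BinaryProfileMatrix, IntensityTable
from .errors import FormatError, ValidationError

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_binary_matrix",
    "write_binary_matrix",
    "read_metadata",
    "write_metadata",
    "read_phylip_distance",
    "write_phylip_distance",
    "tree_to_newick",
    "newick_to_tree",
    "read_newick",
    "write_newick",
]


# -- intensity CSV -----------------------------------------------------------

def read_intensity_table(
    path, delimiter: str = ",", decimal: str = "."
) -> IntensityTable:
    """Read a fragment-intensity CSV.

    The header must name the five columns
    ``isolate_id, replicate, plate_id, locus_id, intensity`` (any order;
    extra columns are ignored).  Violations are reported with 1-based data
    line numbers (header = line 1).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in INTENSITY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        rows = []
        problems = []
        seen: dict[tuple, int] = {}
        for lineno, rec in enumerate(reader, start=2):
            try:
                rep = int(rec["replicate"])
                intensity = float(rec["intensity"].replace(decimal, "."))
            except (TypeError, ValueError):
                problems.append(f"line {lineno}: unparsable replicate/intensity")
                continue
            if rep not in (1, 2):
                problems.append(f"line {lineno}: replicate must be 1 or 2, got {rep}")
                continue
            if intensity < 0:
                problems.append(f"line {lineno}: negative intensity {intensity}")
                continue
            key = (rec["isolate_id"], rep, rec["plate_id"], rec["locus_id"])
            if key in seen:
                problems.append(
                    f"line {lineno}: duplicate record for "
                    f"(isolate={key[0]}, replicate={key[1]}, plate={key[2]}, "
                    f"locus={key[3]}) first seen on line {seen[key]}"
                )
                continue
            seen[key] = lineno
            rows.append(
                {
                    "isolate_id": rec["isolate_id"],
                    "replicate": rep,
                    "plate_id": rec["plate_id"],
                    "locus_id": rec["locus_id"],
                    "intensity": intensity,
                }
            )
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems[:10]))
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return IntensityTable(pd.DataFrame(rows))


def write_intensity_table(table: IntensityTable, path, header_lines=()) -> None:
    _write_csv(table.records, path, sep=",", header_lines=header_lines)


# -- binary matrix TSV -------------------------------------------------------

def read_binary_matrix(
    path, sep: str = "\t", transpose: bool = False, metadata: pd.DataFrame | None = None
) -> BinaryProfileMatrix:
    """Read a 0/1 scoring matrix: isolates as rows, loci as header.

    ``transpose=True`` accepts the loci-as-rows orientation.  Non-binary
    entries are reported with 1-based (row, column) data coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        values = None
    if values is None or not np.isin(values, (0.0, 1.0)).all():
        for r in range(df.shape[0]):
            for c in range(df.shape[1]):
                if str(df.iat[r, c]).strip() not in ("0", "1"):
                    raise FormatError(
                        f"{path}: non-binary entry {df.iat[r, c]!r} at "
                        f"(row {r + 1}, column {c + 1})"
                    )
        raise FormatError(f"{path}: matrix entries are not all 0/1")
    calls = pd.DataFrame(values.astype(np.int8), index=df.index, columns=df.columns)
    if transpose:
        calls = calls.T
    return BinaryProfileMatrix(calls, metadata=metadata)


def write_binary_matrix(
    matrix: BinaryProfileMatrix, path, sep: str = "\t", header_lines=()
) -> None:
    df = matrix.calls.copy()
    df.index.name = "isolate_id"
    _write_csv(df, path, sep=sep, header_lines=header_lines, index=True)


# -- metadata CSV ------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read an ``isolate_id, area, crop, origin`` CSV (indexed by isolate)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["isolate_id"].duplicated().any():
        dups = df.loc[df["isolate_id"].duplicated(), "isolate_id"].tolist()
        raise ValidationError(f"{path}: duplicate metadata for isolate(s) {dups[:5]}")
    return df.set_index("isolate_id")


def write_metadata(metadata: pd.DataFrame, path, header_lines=()) -> None:
    df = metadata.copy()
    if df.index.name == "isolate_id":
        df = df.reset_index()
    _write_csv(df, path, sep=",", header_lines=header_lines)


# -- PHYLIP square distance matrix -------------------------------------------

def write_phylip_distance(
    dm: DistanceMatrix, path, name_map: dict[str, str] | None = None
) -> None:
    """Write the classic PHYLIP square format: taxon count line, then one
    row per taxon with the name padded to 10 characters.

    Ids longer than 10 characters are an error unless ``name_map`` renames
    them; names colliding after mapping are an error, never silently
    truncated.
    """
    name_map = name_map or {}
    names = []
    for i in dm.ids:
        name = name_map.get(i, i)
        if len(name) > 10:
            raise ValidationError(
                f"id {name!r} exceeds PHYLIP's 10-character limit; supply a "
                "name_map renaming it"
            )
        names.append(name)
    if len(set(names)) != len(names):
        raise ValidationError("PHYLIP names collide after renaming")
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n")
        for name, row in zip(names, dm.data):
            fh.write(name.ljust(10) + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_distance(path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix written by this package."""
    with open(path) as fh:
        first = fh.readline()
        try:
            n = int(first.strip())
        except ValueError:
            raise FormatError(f"{path}: first line must be the taxon count")
        ids, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            ids.append(line[:10].strip())
            rows.append([float(v) for v in line[10:].split()])
    if len(ids) != n:
        raise FormatError(f"{path}: expected {n} rows, found {len(ids)}")
    return DistanceMatrix(np.asarray(rows), ids=ids)


# -- Newick ------------------------------------------------------------------

def tree_to_newick(tree: TreeNode) -> str:
    """Serialize a dendrogram; internal node labels carry integer-rounded
    support, branch lengths are parent height minus child height."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(render(c, node.height) for c in node.children)
            label = "" if node.support is None else str(int(round(node.support)))
            body = f"({inner}){label}"
        if parent_height is None:
            return body
        return f"{body}:{_fmt_branch(parent_height - node.height)}"

    return render(tree, None) + ";"


def _fmt_branch(length: float) -> str:
    s = f"{length:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def newick_to_tree(text: str) -> TreeNode:
    """Parse a Newick string (as written here) back into a TreeNode.

    Heights are reconstructed from branch lengths assuming ultrametry:
    every node's height is the maximum branch-length path to a descendant
    leaf, which inverts :func:`tree_to_newick` exactly for ultrametric
    input.  Internal labels are read as supports.
    """
    from Bio import Phylo  # independent, widely used Newick parser

    clade = Phylo.read(_io.StringIO(text), "newick").root

    def convert(cl) -> TreeNode:
        if not cl.clades:
            return TreeNode(name=str(cl.name))
        children = [convert(c) for c in cl.clades]
        height = max(
            child.height + (float(sub.branch_length) if sub.branch_length else 0.0)
            for child, sub in zip(children, cl.clades)
        )
        support = None
        if cl.confidence is not None:
            support = float(cl.confidence)
        elif cl.name not in (None, ""):
            try:
                support = float(cl.name)
            except ValueError:
                pass
        return TreeNode(height=height, support=support, children=children)

    return convert(clade)


def read_newick(path) -> TreeNode:
    return newick_to_tree(Path(path).read_text())


# -- shared helpers ----------------------------------------------------------

def _write_csv(df: pd.DataFrame, path, sep, header_lines=(), index=False) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=index)
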
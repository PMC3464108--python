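"""On-disk formats and the shared in-memory data model.

Colony measurements travel as a tidy :class:`pandas.DataFrame` — one row per
spotted colony — with the column schema in :data:`COLONY_COLUMNS`.  A "plate"
is the subset of rows sharing (``experiment_id``, ``condition``,
``plate_id``); plate geometry is implicit in the grid (every ``row``/``col``
position present exactly once, dead spots recorded with size 0, never
dropped).

Genomic coordinates are BED-style throughout: 0-based, half-open.  Gene sets
arrive as flat GMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

#: Mandatory columns of the colony-table TSV dialect, in canonical order.
COLONY_COLUMNS = [
    "screen_id",
    "experiment_id",
    "condition",
    "temperature",
    "plate_id",
    "row",
    "col",
    "gene",
    "replicate",
    "size",
]

#: Optional column carrying normalized sizes once normalization has run.
NORMALIZED_COLUMN = "size_normalized"

#: Grid positions never spotted with a library strain (partial final plate).
EMPTY_GENE = "EMPTY"

CONDITIONS = ("control", "test")
TEMPERATURES = ("25C", "37C")

#: Gene annotation frame columns (BED4 plus the gene key).
ANNOTATION_COLUMNS = ["gene", "chromosome", "start", "end"]

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PlateGeometry:
    """Row/column extent of one plate grid (1-based positions)."""

    rows: int
    cols: int


def validate_colony_table(df: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    """Validate the colony-table schema and grid invariants.

    Checks mandatory columns, nonnegative sizes, and uniqueness of
    (plate, row, col) within each experiment/condition.  Returns the frame
    with canonical dtypes.  Raises :class:`FormatError` naming the offending
    line (1-based data row, header excluded) where possible.
    """
    missing = [c for c in COLONY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing mandatory column(s) {missing}")

    df = df.copy()
    for col in ("row", "col", "replicate"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["size"] = pd.to_numeric(df["size"], errors="raise").astype(float)
    if NORMALIZED_COLUMN in df.columns:
        df[NORMALIZED_COLUMN] = pd.to_numeric(df[NORMALIZED_COLUMN], errors="coerce")

    bad_size = df.index[df["size"] < 0]
    if len(bad_size):
        raise FormatError(f"{source}: negative size at data line {bad_size[0] + 1}")
    bad_cond = df.index[~df["condition"].isin(CONDITIONS)]
    if len(bad_cond):
        raise FormatError(
            f"{source}: unknown condition {df.loc[bad_cond[0], 'condition']!r} "
            f"at data line {bad_cond[0] + 1}"
        )
    if (df["row"] < 1).any() or (df["col"] < 1).any():
        raise FormatError(f"{source}: grid positions are 1-based; found row/col < 1")

    key = ["experiment_id", "condition", "plate_id", "row", "col"]
    dup = df.duplicated(subset=key)
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0])
        rec = df.iloc[line]
        raise FormatError(
            f"{source}: duplicate grid position "
            f"({rec['plate_id']}, row {rec['row']}, col {rec['col']}) "
            f"at data line {line + 1}"
        )
    return df


def plate_geometry(plate: pd.DataFrame) -> PlateGeometry:
    """Infer a plate's geometry from a complete grid.

    Requires every position of the bounding grid to be present exactly once
    (the colony-table invariant); raises :class:`FormatError` otherwise.
    """
    rows = int(plate["row"].max())
    cols = int(plate["col"].max())
    if len(plate) != rows * cols:
        pid = plate["plate_id"].iloc[0] if len(plate) else "?"
        raise FormatError(
            f"plate {pid}: grid incomplete ({len(plate)} spots for a "
            f"{rows}x{cols} bounding grid)"
        )
    return PlateGeometry(rows=rows, cols=cols)


def iter_plates(df: pd.DataFrame):
    """Yield ((experiment_id, condition, plate_id), plate frame) per plate."""
    yield from df.groupby(["experiment_id", "condition", "plate_id"], sort=True)


def read_colony_table(path) -> pd.DataFrame:
    """Read a colony-size TSV (tab-separated, ``#`` comments) and validate it."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_colony_table(df, source=str(path))


def write_colony_table(df: pd.DataFrame, path) -> None:
    """Write a colony table as TSV, canonical column order, deterministic floats."""
    cols = COLONY_COLUMNS + ([NORMALIZED_COLUMN] if NORMALIZED_COLUMN in df.columns else [])
    out = df.loc[:, cols].sort_values(
        ["experiment_id", "condition", "plate_id", "row", "col"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_bed(path) -> pd.DataFrame:
    """Read BED4 gene coordinates into an annotation frame.

    Returns a frame with columns ``gene, chromosome, start, end`` (0-based,
    half-open).  Raises :class:`FormatError` on ``start >= end``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chromosome", "start", "end", "gene"],
        dtype={"chromosome": str, "gene": str},
    )
    if df.empty:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FormatError(
            f"{path}: start >= end at data line {bad[0] + 1} "
            f"({df.loc[bad[0], 'gene']})"
        )
    if (df["start"] < 0).any():
        raise FormatError(f"{path}: negative start coordinate")
    return df.loc[:, ANNOTATION_COLUMNS]


def write_bed(annotations: pd.DataFrame, path) -> None:
    """Write an annotation frame as BED4."""
    out = annotations.loc[:, ["chromosome", "start", "end", "gene"]]
    out = out.sort_values(["chromosome", "start", "gene"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set_id: [genes...]}``."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import, keep lazy

    try:
        return _read_gmt(str(path))
    except (StopIteration, IndexError):  # empty or header-less file
        return {}


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path, descriptions=None) -> None:
    """Write gene sets as GMT (set, description, members...)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            members = list(gene_sets[set_id])
            desc = descriptions.get(set_id, "na")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def attach_gene_sets(
    annotations: pd.DataFrame, gene_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Add a ``gene_sets`` column (frozenset of memberships) to annotations.

    Set members absent from the annotation are tolerated with a warning, as
    annotation sources and set catalogs rarely share an exact gene universe.
    """
    known = set(annotations["gene"])
    membership: dict[str, set[str]] = {g: set() for g in known}
    unknown: set[str] = set()
    for set_id, members in gene_sets.items():
        for gene in members:
            if gene in membership:
                membership[gene].add(set_id)
            else:
                unknown.add(gene)
    if unknown:
        warnings.warn(
            f"{len(unknown)} gene-set member(s) not in the annotation; ignored",
            stacklevel=2,
        )
    out = annotations.copy()
    out["gene_sets"] = out["gene"].map(lambda g: frozenset(membership[g]))
    return out


def read_gene_list(path) -> list[str]:
    """Read a plain one-gene-per-line list (``#`` comments, blanks ignored)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
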
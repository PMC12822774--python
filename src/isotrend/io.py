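"""Readers and writers for the standard on-disk formats.

Counts come in as MatrixMarket coordinate files with ``features.tsv`` /
``barcodes.tsv`` companions (the common single-cell layout) or as a dense CSV
with isoforms as rows.  The isoform-to-gene mapping is read from a GTF (only
``transcript_id`` / ``gene_id`` attributes are used; coordinates and strand
are irrelevant to the method) or a two-column TSV.  Result tables are plain
TSV with a fixed header so they round-trip losslessly.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import CellTypeAnnotation, IsoformCountMatrix, IsoformGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "read_isoform_gene_map",
    "read_cell_annotation",
    "write_counts_mtx",
    "write_dei_table",
    "read_dei_table",
    "DEI_TABLE_COLUMNS",
]

PathLike = Union[str, Path]

#: Fixed column order of the DEI results table.
DEI_TABLE_COLUMNS = [
    "isoform_id",
    "gene_id",
    "reference",
    "comparison",
    "statistic",
    "statistic_value",
    "ratio_statistic",
    "ratio_value",
    "is_dei",
]


def _read_single_column(path: PathLike, what: str) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    if not ids:
        raise ValueError(f"no {what} ids found in {path}")
    return ids


def read_counts(
    path: PathLike,
    fmt: Optional[str] = None,
    features: Optional[PathLike] = None,
    barcodes: Optional[PathLike] = None,
) -> IsoformCountMatrix:
    """Read an isoform x cell count matrix.

    Parameters
    ----------
    path
        The matrix file: a MatrixMarket ``.mtx`` coordinate file or a CSV
        with a header row of cell ids and isoform ids in the first column.
    fmt
        ``"mtx"`` or ``"csv"``; inferred from the file suffix when omitted.
    features, barcodes
        For MTX input, the row/column id files (first TSV column is used).
        Default to ``features.tsv`` / ``barcodes.tsv`` next to the matrix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        mat = spio.mmread(path)
        iso_ids = _read_single_column(
            features if features is not None else path.parent / "features.tsv",
            "feature",
        )
        cell_ids = _read_single_column(
            barcodes if barcodes is not None else path.parent / "barcodes.tsv",
            "barcode",
        )
        if mat.shape != (len(iso_ids), len(cell_ids)):
            raise ValueError(
                f"matrix declares shape {mat.shape} but id files list "
                f"{len(iso_ids)} features x {len(cell_ids)} barcodes"
            )
        return IsoformCountMatrix(iso_ids, cell_ids, mat)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"non-numeric entries in {path}")
        return IsoformCountMatrix(list(df.index), list(df.columns), values)
    raise ValueError(f"unknown counts format {fmt!r} (expected 'mtx' or 'csv')")


def write_counts_mtx(counts: IsoformCountMatrix, out_dir: PathLike) -> Path:
    """Write counts as ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "matrix.mtx", sparse.coo_matrix(counts.counts), field="integer")
    (out_dir / "features.tsv").write_text("\n".join(counts.isoform_ids) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    return out_dir / "matrix.mtx"


# GTF attributes appear either as `key "value";` (GTF2.2) or `key=value` (GFF
# dialect); both are tolerated since only the id pair is extracted.
_ATTR_RE = {
    key: re.compile(rf'{key}[ =]+"?([^";]+)"?')
    for key in ("transcript_id", "gene_id")
}


def _iter_gtf_pairs(path: PathLike) -> Iterable[tuple[str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            attrs = fields[8]
            tx = _ATTR_RE["transcript_id"].search(attrs)
            if tx is None:
                continue  # gene features etc. carry no transcript_id
            gene = _ATTR_RE["gene_id"].search(attrs)
            if gene is None:
                logger.warning(
                    "%s:%d: transcript %s has no gene_id attribute; skipped",
                    path, lineno, tx.group(1),
                )
                continue
            yield tx.group(1).strip(), gene.group(1).strip()


def read_isoform_gene_map(path: PathLike, fmt: Optional[str] = None) -> IsoformGeneMap:
    """Read the isoform -> gene mapping from a GTF or a 2-column TSV.

    Repeated records for the same transcript are deduplicated; a transcript
    listed under two different genes raises a :class:`ValueError` naming it.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in {".gtf", ".gff", ".gff3"} else "tsv"
    if fmt == "gtf":
        return IsoformGeneMap.from_pairs(_iter_gtf_pairs(path))
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        first = str(df.iloc[0, 0]).lower()
        if first in {"isoform_id", "transcript_id", "isoform", "transcript"}:
            df = df.iloc[1:]
        return IsoformGeneMap.from_pairs(
            (iso, gene) for iso, gene in zip(df.iloc[:, 0], df.iloc[:, 1])
        )
    raise ValueError(f"unknown gene-map format {fmt!r} (expected 'gtf' or 'tsv')")


def read_cell_annotation(path: PathLike) -> CellTypeAnnotation:
    """Read a 2-column (cell_id, cell_type) TSV, with or without a header.

    Duplicate rows with the same label are deduplicated; the same cell with
    two different labels is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"cell_id", "cell", "barcode", "cell_barcode"}:
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for cell, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cell = str(cell)
        if cell in mapping and mapping[cell] != label:
            raise ValueError(
                f"cell {cell!r} annotated as both {mapping[cell]!r} and {label!r}"
            )
        mapping[cell] = label
    return CellTypeAnnotation(mapping)


def write_dei_table(results, path: PathLike) -> None:
    """Write DEI results as a TSV with deterministic row ordering.

    ``results`` may be a list of result records (from :mod:`isotrend.dei`) or
    an already-assembled DataFrame with the standard columns.  Rows are
    sorted by (isoform_id, reference, comparison).
    """
    from .dei import results_to_frame  # local import avoids a cycle

    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = results_to_frame(results)
    for col in DEI_TABLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"results table is missing column {col!r}")
    df = df[DEI_TABLE_COLUMNS].sort_values(
        ["isoform_id", "reference", "comparison"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


def read_dei_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEI_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DEI table columns {missing}")
    df["is_dei"] = df["is_dei"].astype(bool)
    return df
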
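"""Pseudobulk aggregation, candidate filtering and marker detection.

All divergence statistics operate on per-cell-type CPM profiles: raw counts
are summed over the cells of each type and each type's library is scaled to
one million.  Summing before normalising (rather than averaging per-cell CPM)
keeps the profile robust to per-cell depth differences and preserves the
linearity property that a gene's CPM equals the sum of its isoforms' CPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .types import CellTypeAnnotation, DeiConfig, IsoformCountMatrix, IsoformGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "PseudobulkProfile",
    "CandidateSet",
    "MajorIsoformAssignment",
    "select_cell_types",
    "aggregate_pseudobulk",
    "gene_profile",
    "compute_expression_stats",
    "filter_candidates",
    "assign_major_isoforms",
    "detect_markers",
]

CPM_SCALE = 1e6
#: Per-cell scale factor for marker-test normalisation.
CELL_SCALE = 1e4
#: Pseudocount protecting the marker log fold change against zeros.
LOGFC_PSEUDOCOUNT = 1e-9


@dataclass
class PseudobulkProfile:
    """Cell-type x isoform CPM matrix with the per-type library sizes.

    ``cpm[t, i]`` is counts-per-million of isoform ``i`` in cell type
    ``cell_types[t]``; every row with a positive library sums to 1e6.
    """

    cell_types: list[str]
    isoform_ids: list[str]
    cpm: np.ndarray
    lib_sizes: np.ndarray
    zero_types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._iso_index = {i: k for k, i in enumerate(self.isoform_ids)}
        self._type_index = {t: k for k, t in enumerate(self.cell_types)}

    def vector(self, isoform_id: str) -> np.ndarray:
        """CPM of one isoform across cell types (profile order)."""
        return self.cpm[:, self._iso_index[isoform_id]]

    def type_loc(self, label: str) -> int:
        return self._type_index[label]

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cpm, index=self.cell_types, columns=self.isoform_ids)


@dataclass
class CandidateSet:
    """Per-isoform candidate statistics and (after filtering) pass flags.

    Attributes
    ----------
    table
        One row per isoform: ``gene_id``, ``gene_fraction``, ``pct_max`` and,
        once :func:`filter_candidates` has run, ``passed`` and ``reasons``.
    pct
        Isoform x cell-type fraction of cells with count > 0.
    """

    table: pd.DataFrame
    pct: pd.DataFrame
    filtered: bool = False

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def passed_ids(self) -> list[str]:
        if not self.filtered:
            raise ValueError("candidates have not been filtered yet")
        return list(self.table.index[self.table["passed"]])


@dataclass
class MajorIsoformAssignment:
    """gene_id -> most highly expressed isoform over the selected types."""

    mapping: dict[str, str]
    zero_expression_genes: set[str] = field(default_factory=set)

    def __getitem__(self, gene_id: str) -> str:
        return self.mapping[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.mapping

    def items(self):
        return self.mapping.items()


def _annotated_cells(
    counts: IsoformCountMatrix, ann: CellTypeAnnotation
) -> list[str]:
    """Cells present in both matrix and annotation; warn about the rest."""
    cells = [c for c in counts.cell_ids if c in ann]
    dropped = counts.n_cells - len(cells)
    if dropped:
        logger.warning("%d cells lack a cell-type annotation and are dropped", dropped)
    if not cells:
        raise ValueError("no annotated cells present in the count matrix")
    return cells


def _type_indicator(
    cells: Sequence[str], ann: CellTypeAnnotation
) -> tuple[list[str], sparse.csr_matrix]:
    """Sparse cells x types 0/1 membership matrix (types sorted)."""
    labels = sorted({ann[c] for c in cells})
    loc = {t: k for k, t in enumerate(labels)}
    cols = np.fromiter((loc[ann[c]] for c in cells), dtype=np.int64, count=len(cells))
    ind = sparse.csr_matrix(
        (np.ones(len(cells)), (np.arange(len(cells)), cols)),
        shape=(len(cells), len(labels)),
    )
    return labels, ind


def select_cell_types(
    counts: IsoformCountMatrix,
    ann: CellTypeAnnotation,
    keep: Sequence[str],
) -> tuple[IsoformCountMatrix, CellTypeAnnotation]:
    """Restrict matrix and annotation to cells of the given cell types.

    Three to five groups is the recommended working range for the
    multi-cell-type statistic; other sizes are allowed (pair analyses use 2)
    but logged as a warning.
    """
    available = set(ann.values())
    unknown = sorted(set(keep) - available)
    if unknown:
        raise ValueError(f"unknown cell-type labels: {unknown}")
    if not 3 <= len(keep) <= 5:
        logger.warning(
            "%d cell types selected; 3-5 groups are recommended for multi-mode",
            len(keep),
        )
    keepset = set(keep)
    cells = [c for c in counts.cell_ids if c in ann and ann[c] in keepset]
    if not cells:
        raise ValueError("no cells remain after cell-type selection")
    return counts.subset_cells(cells), ann.restrict(cells)


def aggregate_pseudobulk(
    counts: IsoformCountMatrix, ann: CellTypeAnnotation
) -> PseudobulkProfile:
    """Sum raw counts per cell type, then scale each type to CPM.

    A cell type whose cells carry zero total counts is flagged in
    ``zero_types`` and keeps an all-zero CPM row.
    """
    cells = _annotated_cells(counts, ann)
    sub = counts.subset_cells(cells)
    labels, ind = _type_indicator(cells, ann)
    raw = np.asarray((sub.counts @ ind).todense()).T  # types x isoforms
    lib = raw.sum(axis=1)
    cpm = np.zeros_like(raw, dtype=float)
    nz = lib > 0
    cpm[nz] = raw[nz] / lib[nz, None] * CPM_SCALE
    zero_types = {labels[i] for i in np.nonzero(~nz)[0]}
    if zero_types:
        logger.warning("cell types with zero total counts: %s", sorted(zero_types))
    return PseudobulkProfile(
        cell_types=labels,
        isoform_ids=list(sub.isoform_ids),
        cpm=cpm,
        lib_sizes=lib.astype(float),
        zero_types=zero_types,
    )


def gene_profile(pb: PseudobulkProfile, gmap: IsoformGeneMap) -> pd.DataFrame:
    """Cell-type x gene CPM: the sum of each gene's isoform CPM columns.

    By linearity of CPM this equals the CPM computed from summed gene counts.
    Isoforms absent from the mapping are ignored.
    """
    mapped = [i for i in pb.isoform_ids if i in gmap]
    frame = pb.to_frame()[mapped]
    genes = pd.Index([gmap[i] for i in mapped], name="gene_id")
    return frame.T.groupby(genes).sum().T


def compute_expression_stats(
    counts: IsoformCountMatrix,
    ann: CellTypeAnnotation,
    gmap: IsoformGeneMap,
) -> CandidateSet:
    """Detection rates per cell type and each isoform's share of its gene.

    ``pct[iso, type]`` is the fraction of that type's cells with count > 0.
    ``gene_fraction`` pools raw counts over all selected cells: isoform total
    divided by its gene's total (0 when the gene total is 0).  Isoforms
    missing from the gene map are excluded with a warning.
    """
    cells = _annotated_cells(counts, ann)
    sub = counts.subset_cells(cells)
    mapped = [i for i in sub.isoform_ids if i in gmap]
    n_missing = sub.n_isoforms - len(mapped)
    if n_missing:
        logger.warning("%d isoforms absent from the gene map are excluded", n_missing)
    if not mapped:
        raise ValueError("no isoform in the count matrix is present in the gene map")
    sub = sub.subset_isoforms(mapped)

    labels, ind = _type_indicator(cells, ann)
    cells_per_type = np.asarray(ind.sum(axis=0)).ravel()
    detected = sub.counts.copy()
    detected.data = np.ones_like(detected.data)
    pct = np.asarray((detected @ ind).todense()) / cells_per_type[None, :]
    pct_df = pd.DataFrame(pct, index=mapped, columns=labels)

    iso_tot = np.asarray(sub.counts.sum(axis=1)).ravel().astype(float)
    genes = pd.Index([gmap[i] for i in mapped])
    gene_tot = pd.Series(iso_tot).groupby(genes.to_numpy()).sum()
    denom = gene_tot.loc[genes].to_numpy()
    gene_fraction = np.divide(
        iso_tot, denom, out=np.zeros_like(iso_tot), where=denom > 0
    )

    table = pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "gene_fraction": gene_fraction,
            "pct_max": pct_df.max(axis=1).to_numpy(),
        },
        index=pd.Index(mapped, name="isoform_id"),
    )
    return CandidateSet(table=table, pct=pct_df)


def filter_candidates(
    stats: CandidateSet,
    cfg: DeiConfig,
    markers: Optional[Iterable[str]] = None,
) -> CandidateSet:
    """Apply the candidate filters and record per-isoform failure reasons.

    An isoform passes when its detection rate reaches ``min_pct`` in at least
    one selected cell type AND its gene fraction is strictly greater than
    ``gene_fraction_min`` AND, if a marker list is supplied, it is a marker.
    """
    table = stats.table.copy()
    reasons: list[str] = []
    marker_set = set(markers) if markers is not None else None
    reason_col = []
    for iso, row in table.iterrows():
        r = []
        if row["pct_max"] < cfg.min_pct:
            r.append("min_pct")
        if not row["gene_fraction"] > cfg.gene_fraction_min:
            r.append("gene_fraction")
        if marker_set is not None and iso not in marker_set:
            r.append("not_marker")
        reason_col.append(";".join(r))
    table["reasons"] = reason_col
    table["passed"] = table["reasons"] == ""
    logger.info(
        "candidate filtering: %d of %d isoforms pass", int(table["passed"].sum()), len(table)
    )
    return CandidateSet(table=table, pct=stats.pct, filtered=True)


def assign_major_isoforms(
    pb: PseudobulkProfile, gmap: IsoformGeneMap
) -> MajorIsoformAssignment:
    """The gene's isoform with the highest CPM summed over the selected types.

    Ties break to the lexicographically smallest isoform id.  A gene with no
    expressed isoform gets its lexicographically smallest isoform and is
    flagged in ``zero_expression_genes``.
    """
    summed = pd.Series(pb.cpm.sum(axis=0), index=pb.isoform_ids)
    mapping: dict[str, str] = {}
    zero_genes: set[str] = set()
    for gene in gmap.genes:
        members = [i for i in gmap.isoforms_of(gene) if i in summed.index]
        if not members:
            continue
        values = summed.loc[members]
        if values.max() <= 0:
            zero_genes.add(gene)
        # sorted() is stable: among equal CPM the smallest id wins
        mapping[gene] = sorted(members, key=lambda i: (-values[i], i))[0]
    if zero_genes:
        logger.warning("%d genes have no expressed isoform", len(zero_genes))
    return MajorIsoformAssignment(mapping=mapping, zero_expression_genes=zero_genes)


def detect_markers(
    counts: IsoformCountMatrix,
    ann: CellTypeAnnotation,
    cfg: DeiConfig,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per cell type.

    Expression is normalised per cell to ``CELL_SCALE`` total and log1p
    transformed; the two-sided rank-sum test compares each cell type's cells
    against all others.  ``avg_log2FC`` is the base-2 log ratio of mean
    normalised (pre-log) expression, with a small pseudocount.  An isoform is
    reported for a type when |avg_log2FC| exceeds the configured threshold
    and the (optionally Bonferroni-corrected) p-value is below it.  Cell
    types with fewer than 3 cells are skipped; all-zero isoforms are excluded
    before testing.

    Returns a DataFrame with columns isoform_id, cell_type, avg_log2FC,
    p_value, sorted by (cell_type, isoform_id).
    """
    cells = _annotated_cells(counts, ann)
    sub = counts.subset_cells(cells)
    labels = sorted({ann[c] for c in cells})
    if len(labels) < 2:
        raise ValueError("marker detection needs at least two cell types")

    expressed = np.asarray(sub.counts.sum(axis=1)).ravel() > 0
    iso_ids = [i for i, keep in zip(sub.isoform_ids, expressed) if keep]
    X = sub.counts[np.nonzero(expressed)[0], :]

    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0
    norm = np.asarray((X.multiply(CELL_SCALE / totals[None, :])).todense())
    logn = np.log1p(norm)

    type_of = np.array([ann[c] for c in cells])
    n_tests = 0
    rows = []
    for label in labels:
        in_group = type_of == label
        if in_group.sum() < 3:
            logger.warning("cell type %s has <3 cells; marker test skipped", label)
            continue
        x, y = logn[:, in_group], logn[:, ~in_group]
        # identical constant rows would make the U test degenerate; scipy
        # handles ties, but a fully tied row is reported as p=1 below
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
        tied = (x.min(axis=1) == x.max(axis=1)) & (y.min(axis=1) == y.max(axis=1)) & (
            x[:, 0] == y[:, 0]
        )
        pvals[tied] = 1.0
        mean_in = norm[:, in_group].mean(axis=1)
        mean_rest = norm[:, ~in_group].mean(axis=1)
        lfc = np.log2(
            (mean_in + LOGFC_PSEUDOCOUNT) / (mean_rest + LOGFC_PSEUDOCOUNT)
        )
        n_tests += len(iso_ids)
        for iso, l, p in zip(iso_ids, lfc, pvals):
            rows.append((iso, label, float(l), float(p)))

    df = pd.DataFrame(rows, columns=["isoform_id", "cell_type", "avg_log2FC", "p_value"])
    if df.empty:
        return df
    p = df["p_value"] * n_tests if cfg.marker_bonferroni else df["p_value"]
    keep = (df["avg_log2FC"].abs() > cfg.marker_logfc_threshold) & (
        p < cfg.marker_p_threshold
    )
    return (
        df[keep]
        .sort_values(["cell_type", "isoform_id"], kind="mergesort")
        .reset_index(drop=True)
    )
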
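"""Shared domain containers.

The method operates on three inputs: an isoform-by-cell count matrix, a
cell -> cell-type annotation, and an isoform -> gene mapping.  The containers
here validate the structural invariants those inputs must satisfy (unique
identifiers, non-negative integer counts, single-gene membership) so that the
statistical modules can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "IsoformCountMatrix",
    "CellTypeAnnotation",
    "IsoformGeneMap",
    "DeiConfig",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


class IsoformCountMatrix:
    """Sparse isoform x cell matrix of non-negative integer counts.

    Parameters
    ----------
    isoform_ids
        Row identifiers (unique).
    cell_ids
        Column identifiers (unique).
    counts
        Anything convertible to ``scipy.sparse.csr_matrix`` with shape
        ``(len(isoform_ids), len(cell_ids))``.  Entries must be integral
        and >= 0.
    """

    __slots__ = ("isoform_ids", "cell_ids", "counts", "_iso_index", "_cell_index")

    def __init__(
        self,
        isoform_ids: Sequence[str],
        cell_ids: Sequence[str],
        counts,
    ) -> None:
        self.isoform_ids = [str(i) for i in isoform_ids]
        self.cell_ids = [str(c) for c in cell_ids]
        _check_unique(self.isoform_ids, "isoform")
        _check_unique(self.cell_ids, "cell")
        mat = sparse.csr_matrix(counts)
        if mat.shape != (len(self.isoform_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {mat.shape} does not match "
                f"{len(self.isoform_ids)} isoforms x {len(self.cell_ids)} cells"
            )
        if mat.nnz:
            data = mat.data
            if np.any(data < 0):
                raise ValueError("negative counts are not allowed")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
        self.counts = sparse.csr_matrix(
            (np.asarray(np.round(mat.data), dtype=np.int64), mat.indices, mat.indptr),
            shape=mat.shape,
        )
        self._iso_index = {i: k for k, i in enumerate(self.isoform_ids)}
        self._cell_index = {c: k for k, c in enumerate(self.cell_ids)}

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_isoforms(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def iso_loc(self, isoform_id: str) -> int:
        return self._iso_index[isoform_id]

    def cell_loc(self, cell_id: str) -> int:
        return self._cell_index[cell_id]

    def total(self) -> int:
        return int(self.counts.sum())

    def subset_cells(self, cell_ids: Sequence[str]) -> "IsoformCountMatrix":
        """Restrict to the given cells, preserving the given order."""
        cols = [self._cell_index[c] for c in cell_ids]
        return IsoformCountMatrix(self.isoform_ids, list(cell_ids), self.counts[:, cols])

    def subset_isoforms(self, isoform_ids: Sequence[str]) -> "IsoformCountMatrix":
        rows = [self._iso_index[i] for i in isoform_ids]
        return IsoformCountMatrix(list(isoform_ids), self.cell_ids, self.counts[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.isoform_ids, columns=self.cell_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IsoformCountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"IsoformCountMatrix({self.n_isoforms} isoforms x {self.n_cells} cells, "
            f"{self.counts.nnz} nonzero)"
        )


class CellTypeAnnotation(Mapping[str, str]):
    """Mapping ``cell_id -> cell-type label``.

    Labels must be non-empty strings; cell ids are unique by construction of
    the mapping.
    """

    __slots__ = ("_mapping",)

    def __init__(self, mapping: Mapping[str, str]) -> None:
        clean: dict[str, str] = {}
        for cell, label in mapping.items():
            label = str(label).strip()
            if not label:
                raise ValueError(f"empty cell-type label for cell {cell!r}")
            clean[str(cell)] = label
        self._mapping = clean

    def __getitem__(self, cell_id: str) -> str:
        return self._mapping[cell_id]

    def __iter__(self):
        return iter(self._mapping)

    def __len__(self) -> int:
        return len(self._mapping)

    @property
    def labels(self) -> list[str]:
        """Distinct cell-type labels, sorted."""
        return sorted(set(self._mapping.values()))

    def cells_with(self, label: str) -> list[str]:
        return [c for c, l in self._mapping.items() if l == label]

    def restrict(self, cell_ids: Iterable[str]) -> "CellTypeAnnotation":
        """Annotation limited to the given cells (missing cells dropped)."""
        return CellTypeAnnotation(
            {c: self._mapping[c] for c in cell_ids if c in self._mapping}
        )

    def relabeled(self, cell_ids: Sequence[str], labels: Sequence[str]) -> "CellTypeAnnotation":
        return CellTypeAnnotation(dict(zip(cell_ids, labels)))


class IsoformGeneMap(Mapping[str, str]):
    """Mapping ``isoform_id -> gene_id`` (each isoform has exactly one gene)."""

    __slots__ = ("_mapping", "_by_gene")

    def __init__(self, mapping: Mapping[str, str]) -> None:
        self._mapping = {str(i): str(g) for i, g in mapping.items()}
        by_gene: dict[str, list[str]] = {}
        for iso, gene in self._mapping.items():
            by_gene.setdefault(gene, []).append(iso)
        self._by_gene = {g: sorted(isos) for g, isos in by_gene.items()}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IsoformGeneMap":
        """Build from (isoform, gene) pairs, rejecting conflicting duplicates."""
        mapping: dict[str, str] = {}
        for iso, gene in pairs:
            iso, gene = str(iso), str(gene)
            if iso in mapping and mapping[iso] != gene:
                raise ValueError(
                    f"transcript {iso!r} maps to both {mapping[iso]!r} and {gene!r}"
                )
            mapping[iso] = gene
        return cls(mapping)

    def __getitem__(self, isoform_id: str) -> str:
        return self._mapping[isoform_id]

    def __iter__(self):
        return iter(self._mapping)

    def __len__(self) -> int:
        return len(self._mapping)

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def isoforms_of(self, gene_id: str) -> list[str]:
        return list(self._by_gene[gene_id])


@dataclass(frozen=True)
class DeiConfig:
    """Thresholds and options controlling candidate filtering and DEI calls.

    Attributes
    ----------
    min_pct
        An isoform must be detected (count > 0) in at least this fraction of
        cells in at least one selected cell type.  0.25 by default; lower it
        (e.g. 0.1) for sparse data.
    gene_fraction_min
        The isoform must contribute strictly more than this fraction of its
        parent gene's summed expression over the selected cells.
    adj_r2_threshold
        Multi-cell-type calls require adjusted R^2 below this value.
    ratio_range_threshold
        Multi-cell-type calls require the isoform-to-gene CPM ratio to span
        at least this range across cell types.
    product_pos_threshold, product_neg_threshold
        Two-cell-type calls select a positive Pearson-sign x cosine product
        below ``product_pos_threshold`` or a negative product above
        ``product_neg_threshold``.
    ratio_diff_threshold
        Two-cell-type calls additionally require at least this absolute
        change in the isoform-to-gene CPM ratio between the two types.
    marker_logfc_threshold, marker_p_threshold
        One-vs-rest marker prefilter cutoffs (|avg log2 fold change| and raw
        Wilcoxon p-value).
    marker_bonferroni
        Apply a Bonferroni correction to marker p-values (off by default).
    n_group_min
        Recommended minimum number of selected cell types for multi-mode.
    predictor_count
        Number of regression predictors; the statistic is defined with a
        single predictor, so this is fixed at 1.
    """

    min_pct: float = 0.25
    gene_fraction_min: float = 0.10
    adj_r2_threshold: float = 0.2
    ratio_range_threshold: float = 0.05
    product_pos_threshold: float = 0.9
    product_neg_threshold: float = -1.0
    ratio_diff_threshold: float = 0.05
    marker_logfc_threshold: float = 1.0
    marker_p_threshold: float = 0.05
    marker_bonferroni: bool = False
    n_group_min: int = 3
    predictor_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pct <= 1.0:
            raise ValueError("min_pct must lie in [0, 1]")
        if not 0.0 <= self.gene_fraction_min <= 1.0:
            raise ValueError("gene_fraction_min must lie in [0, 1]")
        if self.adj_r2_threshold > 1.0:
            raise ValueError("adj_r2_threshold cannot exceed 1")
        if self.ratio_range_threshold < 0 or self.ratio_diff_threshold < 0:
            raise ValueError("ratio thresholds must be non-negative")
        if not 0.0 <= self.product_pos_threshold <= 1.0:
            raise ValueError("product_pos_threshold must lie in [0, 1]")
        if not -1.0 <= self.product_neg_threshold <= 0.0:
            raise ValueError("product_neg_threshold must lie in [-1, 0]")
        if self.marker_p_threshold <= 0 or self.marker_p_threshold > 1:
            raise ValueError("marker_p_threshold must lie in (0, 1]")
        if self.n_group_min < 2:
            raise ValueError("n_group_min must be >= 2")
        if self.predictor_count != 1:
            raise ValueError("the divergence statistic is defined with exactly one predictor")
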
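"""Divergence statistics and DEI calling rules.

A differentially expressed isoform (DEI) is an isoform whose CPM profile
across cell types diverges from a reference profile: its parent gene (the sum
of the gene's isoform CPM) or the gene's major isoform.

Two regimes, matching the number of selected cell types:

* **multi** (n >= 3 types): the adjusted coefficient of determination of a
  single-predictor linear regression between the isoform vector and the
  reference vector,

      R2_adj = 1 - (1 - r^2) (n - 1) / (n - k - 1),   k = 1,

  with r the Pearson correlation.  Low R2_adj means the reference explains
  little of the isoform's profile.  Calls additionally require the
  isoform-to-gene CPM ratio to span a minimum range across types.  Note the
  statistic is blind to sign: a perfectly anti-correlated isoform has
  R2_adj = 1 and is not called; such cases are flagged via ``negative_r``.

* **pair** (n = 2 types): with two points the Pearson correlation degenerates
  to the sign of the trend, +1 or -1; cosine similarity of the two CPM
  vectors supplies the magnitude.  Their product is near +1 only when the
  isoform tracks the reference, so small positive or any negative products
  are selected, then retained as DEI if the isoform-to-gene ratio changes
  enough between the two types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    CandidateSet,
    MajorIsoformAssignment,
    PseudobulkProfile,
    gene_profile,
)
from .types import DeiConfig, IsoformGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "TrendSimilarity",
    "ExpressionRatios",
    "MultiDeiResult",
    "PairDeiResult",
    "adjusted_r_squared",
    "trend_similarity",
    "expression_ratios",
    "call_multi_dei",
    "call_pair_dei",
    "results_to_frame",
]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def pearson_or_zero(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation, defined as 0 when either vector has no variance.

    A flat reference explains nothing, so the zero-variance convention sends
    the adjusted R^2 to its k=1 floor rather than propagating a NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = float(dx @ dy) / math.sqrt(vx * vy)
    return max(-1.0, min(1.0, r))  # guard rounding on collinear input


def adjusted_r_squared(x: Sequence[float], y: Sequence[float], k: int = 1) -> float:
    """Adjusted R^2 of the single-predictor regression between x and y.

    Symmetric in its arguments (only r^2 enters).  Requires n >= 3 so the
    residual degrees of freedom n - k - 1 are positive; with two cell types
    use the pair statistics instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < k + 2:
        raise ValueError(
            f"adjusted R^2 needs at least {k + 2} cell types (got {n}); "
            "use the pair (two-cell-type) statistics for n = 2"
        )
    r = pearson_or_zero(x, y)
    return 1.0 - (1.0 - r * r) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class TrendSimilarity:
    """Two-cell-type trend comparison.

    ``pearson`` is +1.0 / -1.0, or ``None`` when either vector is constant
    (no trend to compare); ``product`` treats an undefined Pearson as 0.
    ``degenerate`` marks the both-vectors-zero case, which is excluded from
    calling.
    """

    pearson: Optional[float]
    cosine: float
    product: float
    degenerate: bool = False


def trend_similarity(x: Sequence[float], y: Sequence[float]) -> TrendSimilarity:
    """Pearson sign, cosine similarity and their product for n = 2 vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (2,) or y.shape != (2,):
        raise ValueError("trend similarity is defined for vectors of length 2")
    nx = float(np.hypot(x[0], x[1]))
    ny = float(np.hypot(y[0], y[1]))
    if nx == 0.0 and ny == 0.0:
        return TrendSimilarity(pearson=None, cosine=0.0, product=0.0, degenerate=True)
    if nx == 0.0 or ny == 0.0:
        cosine = 0.0
    else:
        # normalise first: robust to very large or subnormal magnitudes
        cosine = max(-1.0, min(1.0, float((x / nx) @ (y / ny))))
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    if dx == 0.0 or dy == 0.0:
        pearson: Optional[float] = None
    else:
        pearson = 1.0 if dx * dy > 0 else -1.0
    product = (pearson if pearson is not None else 0.0) * cosine
    return TrendSimilarity(pearson=pearson, cosine=cosine, product=product)


@dataclass(frozen=True)
class ExpressionRatios:
    """Isoform-to-gene CPM ratios across cell types and their spread."""

    ratios: np.ndarray
    ratio_range: float
    ratio_difference: Optional[float]  # defined for n = 2 only


def expression_ratios(iso_cpm: Sequence[float], gene_cpm: Sequence[float]) -> ExpressionRatios:
    """Per-type isoform/gene CPM ratios; ratio is 0 where the gene CPM is 0."""
    iso = np.asarray(iso_cpm, dtype=float)
    gene = np.asarray(gene_cpm, dtype=float)
    if iso.shape != gene.shape:
        raise ValueError("vectors must have equal length")
    ratios = np.divide(iso, gene, out=np.zeros_like(iso), where=gene > 0)
    ratio_range = float(ratios.max() - ratios.min())
    ratio_difference = float(abs(ratios[0] - ratios[1])) if iso.size == 2 else None
    return ExpressionRatios(ratios=ratios, ratio_range=ratio_range,
                            ratio_difference=ratio_difference)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiDeiResult:
    isoform_id: str
    gene_id: str
    reference: str  # "gene" | "major_isoform"
    adj_r2: float
    ratio_range: float
    is_dei: bool
    negative_r: bool = False


@dataclass(frozen=True)
class PairDeiResult:
    isoform_id: str
    gene_id: str
    reference: str  # "gene" | "major_isoform"
    cell_type_pair: tuple[str, str]
    pearson: Optional[float]
    cosine: float
    product: float
    ratio_difference: float
    is_dei: bool
    degenerate: bool = False
    suppressed: bool = False


def pair_product_selected(product: float, cfg: DeiConfig) -> bool:
    """The sign-branched product selection rule.

    Positive products (trend agrees) are selected when below
    ``product_pos_threshold``; negative products (trend opposes) when above
    ``product_neg_threshold``.  A product of exactly 0 — maximal directional
    divergence, e.g. expression confined to opposite cell types — falls in
    the positive branch and is selected.
    """
    if product >= 0:
        return product < cfg.product_pos_threshold
    return product > cfg.product_neg_threshold


def call_multi_dei(
    candidates: CandidateSet,
    pb: PseudobulkProfile,
    gmap: IsoformGeneMap,
    major: MajorIsoformAssignment,
    cfg: DeiConfig,
) -> list[MultiDeiResult]:
    """Call multi-cell-type DEIs for every passed candidate.

    Each candidate is compared against its gene and, unless it is the major
    isoform itself, against the major isoform.  The ratio-range filter is
    always computed against the gene (the ratio is only defined relative to
    total gene expression).  ``is_dei`` requires
    ``adj_r2 < cfg.adj_r2_threshold`` and
    ``ratio_range >= cfg.ratio_range_threshold``.
    """
    if pb.n_types < 3:
        raise ValueError(
            "multi-mode calling needs at least 3 cell types; "
            "use call_pair_dei for two cell types"
        )
    gcpm = gene_profile(pb, gmap)
    results: list[MultiDeiResult] = []
    for iso in candidates.passed_ids:
        gene = candidates.table.at[iso, "gene_id"]
        x = pb.vector(iso)
        y_gene = gcpm[gene].to_numpy()
        ratios = expression_ratios(x, y_gene)
        for reference, y in (("gene", y_gene), ("major_isoform", None)):
            if reference == "major_isoform":
                if gene not in major or major[gene] == iso:
                    continue
                y = pb.vector(major[gene])
            r = pearson_or_zero(x, y)
            n = pb.n_types
            adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
            results.append(
                MultiDeiResult(
                    isoform_id=iso,
                    gene_id=gene,
                    reference=reference,
                    adj_r2=adj,
                    ratio_range=ratios.ratio_range,
                    is_dei=(adj < cfg.adj_r2_threshold)
                    and (ratios.ratio_range >= cfg.ratio_range_threshold),
                    negative_r=r < 0,
                )
            )
    return results


def call_pair_dei(
    candidates: CandidateSet,
    pb: PseudobulkProfile,
    gmap: IsoformGeneMap,
    major: MajorIsoformAssignment,
    cfg: DeiConfig,
    pair: tuple[str, str],
) -> list[PairDeiResult]:
    """Call pair DEIs between exactly two cell types.

    A candidate is selected by the sign-branched product rule and retained as
    DEI when its isoform-to-gene ratio difference reaches
    ``cfg.ratio_diff_threshold``.  Comparisons against the major isoform are
    suppressed for genes whose major isoform is itself selected against the
    gene on this pair (its divergence would be attributed to the wrong
    reference).  Candidates that are their gene's major isoform are compared
    against the gene only.
    """
    for label in pair:
        if label not in pb.cell_types:
            raise ValueError(f"cell type {label!r} not present in the pseudobulk profile")
    if len(set(pair)) != 2:
        raise ValueError("pair must name two distinct cell types")
    rows = [pb.type_loc(pair[0]), pb.type_loc(pair[1])]
    gcpm = gene_profile(pb, gmap)

    # genes whose major isoform is itself trend-divergent from the gene here
    major_divergent: set[str] = set()
    for gene, iso in major.items():
        if gene not in gcpm.columns:
            continue
        ts = trend_similarity(pb.vector(iso)[rows], gcpm[gene].to_numpy()[rows])
        if not ts.degenerate and pair_product_selected(ts.product, cfg):
            major_divergent.add(gene)

    results: list[PairDeiResult] = []
    for iso in candidates.passed_ids:
        gene = candidates.table.at[iso, "gene_id"]
        x = pb.vector(iso)[rows]
        y_gene = gcpm[gene].to_numpy()[rows]
        ratios = expression_ratios(x, y_gene)
        rdiff = ratios.ratio_difference or 0.0
        for reference in ("gene", "major_isoform"):
            if reference == "major_isoform":
                if gene not in major or major[gene] == iso:
                    continue
                y = pb.vector(major[gene])[rows]
            else:
                y = y_gene
            ts = trend_similarity(x, y)
            suppressed = reference == "major_isoform" and gene in major_divergent
            is_dei = (
                not ts.degenerate
                and not suppressed
                and pair_product_selected(ts.product, cfg)
                and rdiff >= cfg.ratio_diff_threshold
            )
            results.append(
                PairDeiResult(
                    isoform_id=iso,
                    gene_id=gene,
                    reference=reference,
                    cell_type_pair=(pair[0], pair[1]),
                    pearson=ts.pearson,
                    cosine=ts.cosine,
                    product=ts.product,
                    ratio_difference=rdiff,
                    is_dei=is_dei,
                    degenerate=ts.degenerate,
                    suppressed=suppressed,
                )
            )
    return results


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten result records into the standard DEI table layout."""
    rows = []
    for res in results:
        if isinstance(res, MultiDeiResult):
            rows.append(
                (res.isoform_id, res.gene_id, res.reference, "multi",
                 "adj_r2", res.adj_r2, "ratio_range", res.ratio_range, res.is_dei)
            )
        elif isinstance(res, PairDeiResult):
            comparison = "|".join(res.cell_type_pair)
            rows.append(
                (res.isoform_id, res.gene_id, res.reference, comparison,
                 "product", res.product, "ratio_difference", res.ratio_difference,
                 res.is_dei)
            )
        else:
            raise TypeError(f"not a DEI result: {type(res).__name__}")
    return pd.DataFrame(
        rows,
        columns=[
            "isoform_id", "gene_id", "reference", "comparison",
            "statistic", "statistic_value", "ratio_statistic", "ratio_value",
            "is_dei",
        ],
    )
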
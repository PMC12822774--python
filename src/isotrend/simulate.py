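"""Count-level benchmark simulator with planted differential isoforms.

The generator builds a two-condition, two-replicate factorial benchmark:
1000 genes with three isoforms each, exactly one isoform per gene planted as
differential.  Gene abundances are log-normal and shared across conditions,
so at the gene level nothing changes; the differential signal lives purely in
isoform *usage* (the within-gene proportions).

Effect tiers (assigned to genes round-robin):

* ``mild`` / ``moderate`` / ``strong`` — the minor isoform's usage gains
  0.15 / 0.30 / 0.45 in condition 2, siblings renormalised proportionally.
* ``reversed`` — a dominance reversal: the designated (dominant) isoform
  collapses from 0.50 to minor-level usage, so the gene's major isoform
  differs between conditions.  Implemented as a one-sided collapse rather
  than an exact dominant/minor swap so that exactly one isoform per gene
  carries a detectable usage change, matching the one-differential-per-gene
  ground truth.

Bulk samples draw Poisson counts around depth x abundance x usage (a
count-level stand-in for read-level simulation and re-quantification, which
the calling method never sees beyond counts).  Single-cell datasets layer a
negative-binomial cell model with expression-dependent dropout on top of each
bulk sample profile, in the spirit of Splatter/scDesign2-style simulators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .types import CellTypeAnnotation, IsoformCountMatrix, IsoformGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "EffectTier",
    "SimulationDesign",
    "GroundTruth",
    "BulkSimulation",
    "SingleCellDataset",
    "dropout_probability",
    "simulate_bulk",
    "simulate_single_cell",
    "simulate_paired_single_cell",
]


@dataclass(frozen=True)
class EffectTier:
    """A named usage-shift magnitude; ``delta=None`` marks the reversal tier."""

    name: str
    delta: Optional[float]


DEFAULT_TIERS: tuple[EffectTier, ...] = (
    EffectTier("mild", 0.15),
    EffectTier("moderate", 0.30),
    EffectTier("strong", 0.45),
    EffectTier("reversed", None),
)


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial benchmark design.

    Defaults: 1000 genes x 3 isoforms, one differential isoform per gene;
    two conditions x two replicates; bulk depths 0.5M/1M/2M reads; 300/500/
    1000 cells per single-cell dataset.  ``usage_pattern`` orders isoforms
    dominant -> minor within each gene; for the shift tiers the minor isoform
    is the planted differential, for the reversal tier the dominant one
    (drawn from ``reversed_usage_pattern``).
    """

    n_genes: int = 1000
    isoforms_per_gene: int = 3
    n_conditions: int = 2
    n_replicates: int = 2
    depths: tuple[float, ...] = (500_000.0, 1_000_000.0, 2_000_000.0)
    cell_counts: tuple[int, ...] = (300, 500, 1000)
    effect_tiers: tuple[EffectTier, ...] = DEFAULT_TIERS
    usage_pattern: tuple[float, ...] = (0.65, 0.30, 0.05)
    reversed_usage_pattern: tuple[float, ...] = (0.50, 0.45, 0.05)
    abundance_meanlog: float = 4.0
    abundance_sdlog: float = 0.5
    nb_dispersion: float = 0.3
    dropout_midpoint: float = math.log(0.02)
    dropout_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.isoforms_per_gene < 2:
            raise ValueError("need >= 1 gene with >= 2 isoforms each")
        if self.n_conditions != 2:
            raise ValueError("the benchmark design is defined for two conditions")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if any(d <= 0 for d in self.depths) or not self.depths:
            raise ValueError("depths must be positive")
        if any(c <= 0 for c in self.cell_counts) or not self.cell_counts:
            raise ValueError("cell counts must be positive")
        if not self.effect_tiers:
            raise ValueError("at least one effect tier is required")
        for pattern in (self.usage_pattern, self.reversed_usage_pattern):
            if len(pattern) != self.isoforms_per_gene:
                raise ValueError("usage pattern length must equal isoforms_per_gene")
            if any(u < 0 for u in pattern) or not math.isclose(sum(pattern), 1.0):
                raise ValueError("usage pattern must be non-negative and sum to 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    # -- identifiers ----------------------------------------------------
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{g + 1:0{width}d}" for g in range(self.n_genes)]

    def isoform_ids(self) -> list[str]:
        return [
            f"{gene}.T{j + 1}"
            for gene in self.gene_ids()
            for j in range(self.isoforms_per_gene)
        ]

    def gene_map(self) -> IsoformGeneMap:
        return IsoformGeneMap(
            {iso: iso.rsplit(".", 1)[0] for iso in self.isoform_ids()}
        )

    def tier_of(self, gene_index: int) -> EffectTier:
        return self.effect_tiers[gene_index % len(self.effect_tiers)]


@dataclass
class GroundTruth:
    """Planted labels: per isoform, whether it is differential and its tier."""

    table: pd.DataFrame  # index isoform_id; columns gene_id, is_differential, effect_tier

    @property
    def universe(self) -> set[str]:
        return set(self.table.index)

    @property
    def differential(self) -> set[str]:
        return set(self.table.index[self.table["is_differential"]])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class BulkSimulation:
    counts: pd.DataFrame          # isoform x sample raw counts
    samples: pd.DataFrame         # sample sheet: sample, condition, replicate, depth
    gene_map: IsoformGeneMap
    truth: GroundTruth


@dataclass
class SingleCellDataset:
    name: str
    condition: int                # 1-based
    replicate: int                # 1-based
    depth: float
    cell_count: int
    counts: IsoformCountMatrix
    annotation: CellTypeAnnotation


# ---------------------------------------------------------------------------
# model pieces
# ---------------------------------------------------------------------------

def dropout_probability(
    mu: Union[float, np.ndarray],
    midpoint: float = math.log(0.02),
    shape: float = 1.0,
) -> Union[float, np.ndarray]:
    """Expression-dependent dropout: logistic decrease in log expected count.

    ``p = 1 / (1 + exp(shape * (ln(mu + 1e-9) - midpoint)))`` — close to 1
    for vanishing expression, sliding to 0 as the expected count grows, with
    p = 0.5 at ``mu = exp(midpoint)``.
    """
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr < 0):
        raise ValueError("expected counts must be non-negative")
    p = 1.0 / (1.0 + np.exp(shape * (np.log(mu_arr + 1e-9) - midpoint)))
    return float(p) if np.isscalar(mu) else p


def _rng(design: SimulationDesign, *key: int) -> np.random.Generator:
    """Deterministic substream keyed by dataset indices."""
    return np.random.default_rng(np.random.SeedSequence((design.seed, *key)))


def _usage(design: SimulationDesign) -> np.ndarray:
    """Usage proportions, shape (n_conditions, n_genes, isoforms_per_gene)."""
    m = design.isoforms_per_gene
    usage = np.empty((2, design.n_genes, m))
    for g in range(design.n_genes):
        tier = design.tier_of(g)
        if tier.delta is None:  # dominance reversal
            base = np.asarray(design.reversed_usage_pattern, dtype=float)
            cond2 = base.copy()
            minor_level = base[-1]
            cond2[0] = minor_level
            cond2[1:] = base[1:] * (1.0 - minor_level) / (1.0 - base[0])
        else:
            base = np.asarray(design.usage_pattern, dtype=float)
            cond2 = base.copy()
            shifted = base[-1] + tier.delta
            if shifted > 1.0 or shifted < 0.0:
                logger.warning(
                    "gene %d: shifted usage %.3f clipped to [0, 1]", g, shifted
                )
                shifted = min(max(shifted, 0.0), 1.0)
            cond2[-1] = shifted
            rest = base[:-1].sum()
            if rest > 0:
                cond2[:-1] = base[:-1] * (1.0 - shifted) / rest
        usage[0, g] = base / base.sum()
        usage[1, g] = cond2 / cond2.sum()
    return usage


def _differential_index(tier: EffectTier) -> int:
    """Within-gene index of the planted differential isoform (-1 = minor)."""
    return 0 if tier.delta is None else -1


def _ground_truth(design: SimulationDesign) -> GroundTruth:
    genes = design.gene_ids()
    m = design.isoforms_per_gene
    rows = []
    for g, gene in enumerate(genes):
        tier = design.tier_of(g)
        diff_j = _differential_index(tier) % m
        for j in range(m):
            rows.append((f"{gene}.T{j + 1}", gene, j == diff_j, tier.name))
    table = pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "is_differential", "effect_tier"]
    ).set_index("isoform_id")
    return GroundTruth(table=table)


def _relative_abundance(design: SimulationDesign) -> np.ndarray:
    """Expected isoform share of total reads, shape (2, n_isoforms).

    Gene abundances ~ LogNormal(meanlog, sdlog), shared across conditions,
    multiplied by the per-condition usage; each condition's row sums to 1.
    """
    rng = _rng(design, 0)
    abundance = rng.lognormal(design.abundance_meanlog, design.abundance_sdlog,
                              design.n_genes)
    share = abundance / abundance.sum()
    usage = _usage(design)
    rel = (share[None, :, None] * usage).reshape(2, -1)
    return rel / rel.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_bulk(design: SimulationDesign) -> BulkSimulation:
    """Generate the bulk benchmark: one Poisson count table per sample.

    Samples span the full (condition x replicate x depth) factorial — 12
    under defaults — and share the same expected profile within a condition;
    replicates differ only by count noise.
    """
    rel = _relative_abundance(design)
    iso_ids = design.isoform_ids()
    columns: dict[str, np.ndarray] = {}
    sheet = []
    for ci in range(design.n_conditions):
        for ri in range(design.n_replicates):
            for di, depth in enumerate(design.depths):
                rng = _rng(design, 1, ci, ri, di)
                counts = rng.poisson(depth * rel[ci])
                name = f"cond{ci + 1}_rep{ri + 1}_depth{int(depth)}"
                columns[name] = counts
                sheet.append((name, ci + 1, ri + 1, float(depth)))
    counts = pd.DataFrame(columns, index=pd.Index(iso_ids, name="isoform_id"))
    samples = pd.DataFrame(sheet, columns=["sample", "condition", "replicate", "depth"])
    return BulkSimulation(
        counts=counts,
        samples=samples,
        gene_map=design.gene_map(),
        truth=_ground_truth(design),
    )


def _draw_cells(
    design: SimulationDesign,
    rel_row: np.ndarray,
    depth: float,
    cell_count: int,
    rng: np.random.Generator,
) -> sparse.csr_matrix:
    """NB counts with expression-dependent dropout; shape (isoforms, cells)."""
    mu = (depth / cell_count) * rel_row  # per-cell expected count per isoform
    disp = design.nb_dispersion
    if disp > 0:
        n = 1.0 / disp
        p = n / (n + mu)
        raw = rng.negative_binomial(n, p[:, None], size=(mu.size, cell_count))
    else:
        raw = rng.poisson(mu[:, None], size=(mu.size, cell_count))
    p_drop = dropout_probability(mu, design.dropout_midpoint, design.dropout_shape)
    keep = rng.random((mu.size, cell_count)) >= p_drop[:, None]
    return sparse.csr_matrix(raw * keep)


def _dataset_name(ci: int, ri: int, depth: float, cells: int) -> str:
    return f"cond{ci + 1}_rep{ri + 1}_depth{int(depth)}_cells{cells}"


def _single_dataset(
    design: SimulationDesign,
    rel: np.ndarray,
    ci: int,
    ri: int,
    di: int,
    ki: int,
) -> SingleCellDataset:
    depth = design.depths[di]
    cells = design.cell_counts[ki]
    rng = _rng(design, 2, ci, ri, di, ki)
    mat = _draw_cells(design, rel[ci], depth, cells, rng)
    if mat.nnz == 0:
        raise ValueError(
            f"simulated dataset cond{ci + 1}/rep{ri + 1}/depth{depth}/cells{cells} "
            "is all zero; increase depth or decrease dropout"
        )
    name = _dataset_name(ci, ri, depth, cells)
    cell_ids = [f"{name}_cell{j + 1}" for j in range(cells)]
    label = f"condition_{ci + 1}"
    counts = IsoformCountMatrix(design.isoform_ids(), cell_ids, mat)
    annotation = CellTypeAnnotation({c: label for c in cell_ids})
    return SingleCellDataset(
        name=name,
        condition=ci + 1,
        replicate=ri + 1,
        depth=float(depth),
        cell_count=cells,
        counts=counts,
        annotation=annotation,
    )


def simulate_single_cell(
    design: SimulationDesign,
) -> tuple[list[SingleCellDataset], IsoformGeneMap, GroundTruth, pd.DataFrame]:
    """Generate the single-cell benchmark datasets.

    One dataset per (condition, replicate, depth, cell_count) cell of the
    factorial — 36 under defaults.  Each dataset's cells carry their
    condition label; :func:`simulate_paired_single_cell` assembles the two
    matching condition datasets into one two-group matrix for DEI calling.
    """
    rel = _relative_abundance(design)
    datasets = []
    sheet = []
    for ci in range(design.n_conditions):
        for ri in range(design.n_replicates):
            for di, depth in enumerate(design.depths):
                for ki, cells in enumerate(design.cell_counts):
                    ds = _single_dataset(design, rel, ci, ri, di, ki)
                    datasets.append(ds)
                    sheet.append((ds.name, ds.condition, ds.replicate, ds.depth,
                                  ds.cell_count))
    sheet_df = pd.DataFrame(
        sheet, columns=["dataset", "condition", "replicate", "depth", "cell_count"]
    )
    return datasets, design.gene_map(), _ground_truth(design), sheet_df


def simulate_paired_single_cell(
    design: SimulationDesign,
    replicate: int = 1,
    depth: Optional[float] = None,
    cell_count: Optional[int] = None,
) -> tuple[IsoformCountMatrix, CellTypeAnnotation, IsoformGeneMap, GroundTruth]:
    """Both conditions of one factorial cell, merged into a two-group matrix.

    This is the analysis-ready form: ``cell_count`` cells per condition,
    labelled ``condition_1`` / ``condition_2``, drawn from the same
    substreams as :func:`simulate_single_cell` so the paired matrix is a
    column-concatenation of the corresponding single-condition datasets.
    """
    depth = design.depths[0] if depth is None else depth
    cell_count = design.cell_counts[0] if cell_count is None else cell_count
    di = design.depths.index(depth)
    ki = design.cell_counts.index(cell_count)
    ri = replicate - 1
    if not 0 <= ri < design.n_replicates:
        raise ValueError(f"replicate must be in 1..{design.n_replicates}")
    rel = _relative_abundance(design)
    parts = [_single_dataset(design, rel, ci, ri, di, ki) for ci in range(2)]
    mat = sparse.hstack([p.counts.counts for p in parts], format="csr")
    cell_ids = [c for p in parts for c in p.counts.cell_ids]
    counts = IsoformCountMatrix(design.isoform_ids(), cell_ids, mat)
    mapping: dict[str, str] = {}
    for p in parts:
        mapping.update({c: p.annotation[c] for c in p.counts.cell_ids})
    return counts, CellTypeAnnotation(mapping), design.gene_map(), _ground_truth(design)
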
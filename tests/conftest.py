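"""Shared fixtures: a small deterministic dataset with known structure.

The toy dataset has 3 genes x 2 isoforms over 3 cell types x 20 cells.
Counts are constant within a cell type, so pseudobulk CPM values are exact
and every derived statistic can be computed by hand:

* G1: T1a tracks the gene everywhere (constant 50% usage) — never a DEI.
* G2: T2a's usage swings 0.9 / 0.1 / 0.5 across types (T2b mirrors it) —
  clear DEIs in both multi and pair mode.
* G3: single expressed isoform T3a (gene == isoform == major isoform);
  T3b is all-zero.
"""

from __future__ import annotations

import numpy as np
import pytest

from isotrend.types import CellTypeAnnotation, IsoformCountMatrix, IsoformGeneMap

CELL_TYPES = ("alpha", "beta", "gamma")
CELLS_PER_TYPE = 20

#: per-cell counts of each isoform within each cell type
TOY_PROFILE = {
    #            alpha  beta  gamma
    "G1.T1a": (5, 10, 20),
    "G1.T1b": (5, 10, 20),
    "G2.T2a": (18, 2, 10),
    "G2.T2b": (2, 18, 10),
    "G3.T3a": (6, 6, 6),
    "G3.T3b": (0, 0, 0),
}


@pytest.fixture(scope="session")
def toy_dataset():
    isoforms = list(TOY_PROFILE)
    cell_ids = [
        f"{ct}_{i:02d}" for ct in CELL_TYPES for i in range(CELLS_PER_TYPE)
    ]
    counts = np.zeros((len(isoforms), len(cell_ids)), dtype=int)
    for r, iso in enumerate(isoforms):
        for t, ct in enumerate(CELL_TYPES):
            counts[r, t * CELLS_PER_TYPE:(t + 1) * CELLS_PER_TYPE] = TOY_PROFILE[iso][t]
    matrix = IsoformCountMatrix(isoforms, cell_ids, counts)
    ann = CellTypeAnnotation({c: c.split("_")[0] for c in cell_ids})
    gmap = IsoformGeneMap({iso: iso.split(".")[0] for iso in isoforms})
    return matrix, ann, gmap


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
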
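"""Plot-ready tables for the two standard visualisations.

The tested contract is the exported tables: a line-plot table carrying the
exact CPM vectors the DEI statistics consume, and a cell-type x cell-type
Euclidean-distance matrix for one feature.  Rendering (matplotlib) is an
optional convenience on top.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import MajorIsoformAssignment, PseudobulkProfile, gene_profile
from .types import IsoformGeneMap

__all__ = [
    "export_lineplot_table",
    "export_distance_heatmap",
    "plot_lineplot",
    "plot_distance_heatmap",
]


def export_lineplot_table(
    pb: PseudobulkProfile,
    isoform_id: str,
    gmap: IsoformGeneMap,
    major: MajorIsoformAssignment,
) -> pd.DataFrame:
    """CPM of an isoform, its gene and the gene's major isoform per cell type.

    One row per cell type in profile order; the values are exactly the
    vectors the DEI statistics are computed from, so feeding them back into
    :mod:`isotrend.dei` reproduces the reported statistics.
    """
    if isoform_id not in pb.isoform_ids:
        raise KeyError(f"unknown isoform {isoform_id!r}")
    if isoform_id not in gmap:
        raise KeyError(f"isoform {isoform_id!r} is not in the gene map")
    gene = gmap[isoform_id]
    gene_cpm = gene_profile(pb, gmap)[gene].to_numpy()
    return pd.DataFrame(
        {
            "cell_type": pb.cell_types,
            "isoform_cpm": pb.vector(isoform_id),
            "gene_cpm": gene_cpm,
            "major_cpm": pb.vector(major[gene]),
        }
    )


def _feature_vector(
    pb: PseudobulkProfile, feature_id: str, gmap: Optional[IsoformGeneMap]
) -> np.ndarray:
    if feature_id in pb.isoform_ids:
        return pb.vector(feature_id)
    if gmap is not None and feature_id in set(gmap.values()):
        return gene_profile(pb, gmap)[feature_id].to_numpy()
    raise KeyError(f"unknown feature {feature_id!r}")


def export_distance_heatmap(
    pb: PseudobulkProfile,
    feature_id: str,
    gmap: Optional[IsoformGeneMap] = None,
    features: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise expression distances for one feature across cell types.

    ``D[a, b] = |cpm_a - cpm_b|`` — the Euclidean distance between the
    scalar per-type values of the feature (an isoform, or a gene via the
    summed-isoform CPM).  Symmetric with a zero diagonal.

    Passing ``features`` switches to the alternative reading: Euclidean
    distances between the full cross-type CPM vectors of several features.
    """
    if features is not None:
        vecs = {f: _feature_vector(pb, f, gmap) for f in features}
        mat = np.array(
            [
                [float(np.linalg.norm(vecs[a] - vecs[b])) for b in features]
                for a in features
            ]
        )
        return pd.DataFrame(mat, index=list(features), columns=list(features))
    v = _feature_vector(pb, feature_id, gmap)
    mat = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(mat, index=pb.cell_types, columns=pb.cell_types)


def plot_lineplot(table: pd.DataFrame, ax=None):
    """Render a line-plot table (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for col, style in (("isoform_cpm", "-o"), ("gene_cpm", "--s"), ("major_cpm", ":^")):
        ax.plot(table["cell_type"], table[col], style, label=col.replace("_cpm", ""))
    ax.set_ylabel("CPM")
    ax.legend()
    return ax


def plot_distance_heatmap(matrix: pd.DataFrame, ax=None):
    """Render a distance matrix (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(matrix.to_numpy())
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.figure.colorbar(im, ax=ax)
    return ax
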
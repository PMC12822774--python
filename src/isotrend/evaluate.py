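"""Benchmark metrics against planted truth and permutation-based FDR.

The empirical FDR follows the label-permutation recipe: detections on the
true cell-type labels give ``n_detected(t)``; each of ``n_perm`` uniform
label shuffles (preserving group sizes by construction) is re-analysed and
its detections counted as false positives; the FDR at threshold ``t`` is the
mean false-positive count divided by ``n_detected(t)``.  One set of
permutations is shared across the whole threshold grid — detection statistics
do not depend on the threshold, so each labelling is scored once and
thresholded cheaply, which also reduces the across-threshold variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import dei as dei_mod
from .preprocess import (
    aggregate_pseudobulk,
    assign_major_isoforms,
    compute_expression_stats,
    detect_markers,
    filter_candidates,
)
from .simulate import GroundTruth
from .types import CellTypeAnnotation, DeiConfig, IsoformCountMatrix, IsoformGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkMetrics",
    "FdrEstimate",
    "benchmark_calls",
    "benchmark_dataset",
    "empirical_fdr",
    "fdr_to_frame",
]


@dataclass(frozen=True)
class BenchmarkMetrics:
    """Confusion counts and derived rates over the truth universe."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_undefined: bool = False

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "BenchmarkMetrics":
        undefined = (tp + fp) == 0
        precision = 0.0 if undefined else tp / (tp + fp)
        recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
        f1 = (
            0.0
            if precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
        return cls(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1,
                   precision_undefined=undefined)


def benchmark_calls(called: Iterable[str], truth: GroundTruth) -> BenchmarkMetrics:
    """Score a called isoform set against the planted differential set."""
    called = set(called)
    outside = sorted(called - truth.universe)
    if outside:
        raise ValueError(
            f"{len(outside)} called isoforms are outside the truth universe, "
            f"e.g. {outside[:5]}"
        )
    diff = truth.differential
    tp = len(called & diff)
    fp = len(called - diff)
    fn = len(diff - called)
    return BenchmarkMetrics.from_counts(tp, fp, fn)


# ---------------------------------------------------------------------------
# shared detection core
# ---------------------------------------------------------------------------

def _score_candidates(
    counts: IsoformCountMatrix,
    ann: CellTypeAnnotation,
    gmap: IsoformGeneMap,
    cfg: DeiConfig,
    mode: str,
    pair: Optional[tuple[str, str]],
    use_markers: bool = False,
) -> pd.DataFrame:
    """Per-candidate vs-gene detection statistics for one labelling.

    Returns one row per passed candidate with the primary statistic
    (``product`` for pair mode, ``adj_r2`` for multi mode), the companion
    ratio statistic, and a validity flag; thresholding is left to the caller
    so a whole grid can be scanned from one run.  With ``use_markers`` the
    one-vs-rest marker prefilter runs first (on the given labelling, so
    permutation analyses re-run it on permuted labels).
    """
    markers = None
    if use_markers:
        markers = set(detect_markers(counts, ann, cfg)["isoform_id"])
    stats = compute_expression_stats(counts, ann, gmap)
    cand = filter_candidates(stats, cfg, markers=markers)
    pb = aggregate_pseudobulk(counts, ann)
    major = assign_major_isoforms(pb, gmap)
    if mode == "pair":
        if pair is None:
            labels = pb.cell_types
            if len(labels) != 2:
                raise ValueError(
                    f"pair mode needs exactly two cell types (got {len(labels)}); "
                    "pass pair=(a, b) to choose"
                )
            pair = (labels[0], labels[1])
        results = dei_mod.call_pair_dei(cand, pb, gmap, major, cfg, pair)
        rows = [
            (r.isoform_id, r.product, r.ratio_difference, not r.degenerate)
            for r in results
            if r.reference == "gene"
        ]
        return pd.DataFrame(rows, columns=["isoform_id", "statistic", "ratio", "valid"])
    if mode == "multi":
        results = dei_mod.call_multi_dei(cand, pb, gmap, major, cfg)
        rows = [
            (r.isoform_id, r.adj_r2, r.ratio_range, True)
            for r in results
            if r.reference == "gene"
        ]
        return pd.DataFrame(rows, columns=["isoform_id", "statistic", "ratio", "valid"])
    raise ValueError(f"unknown mode {mode!r} (expected 'pair' or 'multi')")


def _detected_at(scores: pd.DataFrame, t: float, cfg: DeiConfig, mode: str) -> np.ndarray:
    """Boolean detection mask at primary threshold ``t``."""
    s = scores["statistic"].to_numpy()
    ratio = scores["ratio"].to_numpy()
    valid = scores["valid"].to_numpy()
    if mode == "pair":
        selected = np.where(
            s >= 0, s < t, s > cfg.product_neg_threshold
        )
        return valid & selected & (ratio >= cfg.ratio_diff_threshold)
    return valid & (s < t) & (ratio >= cfg.ratio_range_threshold)


def benchmark_dataset(
    counts: IsoformCountMatrix,
    ann: CellTypeAnnotation,
    gmap: IsoformGeneMap,
    truth: GroundTruth,
    cfg: DeiConfig,
    mode: str = "pair",
    pair: Optional[tuple[str, str]] = None,
    use_markers: bool = True,
) -> BenchmarkMetrics:
    """Run vs-gene DEI detection on a dataset and score it against truth.

    By default the full workflow is scored, including the marker prefilter
    that opens it: without that step, compensating usage changes in sibling
    isoforms of a truly differential isoform are also called (they do change
    their gene ratio) and are counted as false positives against a
    one-differential-per-gene truth.
    """
    scores = _score_candidates(counts, ann, gmap, cfg, mode, pair,
                               use_markers=use_markers)
    t = cfg.product_pos_threshold if mode == "pair" else cfg.adj_r2_threshold
    mask = _detected_at(scores, t, cfg, mode)
    called = set(scores.loc[mask, "isoform_id"])
    return benchmark_calls(called, truth)


# ---------------------------------------------------------------------------
# empirical FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FdrEstimate:
    """Permutation FDR at one detection threshold.

    ``fdr`` is capped at 1 for reporting; ``fdr_raw`` keeps the raw ratio.
    ``undefined`` marks thresholds with no detections on the true labels
    (fdr reported as 0).
    """

    threshold: float
    mean_fp: float
    n_detected: int
    fdr: float
    fdr_raw: float
    undefined: bool = False


def empirical_fdr(
    counts: IsoformCountMatrix,
    ann: CellTypeAnnotation,
    gmap: IsoformGeneMap,
    cfg: DeiConfig,
    mode: str = "pair",
    threshold_grid: Sequence[float] = (0.9,),
    n_perm: int = 100,
    seed: int = 0,
    pair: Optional[tuple[str, str]] = None,
    use_markers: bool = False,
) -> list[FdrEstimate]:
    """Empirical FDR over a grid of primary detection thresholds.

    The grid scans ``product_pos_threshold`` in pair mode and
    ``adj_r2_threshold`` in multi mode; all other configuration values are
    held at ``cfg``.  With ``use_markers`` the marker prefilter is re-run on
    every permuted labelling, keeping the permuted analyses exchangeable with
    the true one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = list(threshold_grid)
    if not grid:
        raise ValueError("threshold_grid must be non-empty")

    cells = [c for c in counts.cell_ids if c in ann]
    labels = np.array([ann[c] for c in cells])

    true_scores = _score_candidates(counts, ann, gmap, cfg, mode, pair,
                                    use_markers=use_markers)
    n_detected = {
        t: int(_detected_at(true_scores, t, cfg, mode).sum()) for t in grid
    }

    rng = np.random.default_rng(seed)
    fp_counts = {t: np.zeros(n_perm) for t in grid}
    for b in range(n_perm):
        shuffled = labels[rng.permutation(len(labels))]
        ann_b = CellTypeAnnotation(dict(zip(cells, shuffled)))
        scores_b = _score_candidates(counts, ann_b, gmap, cfg, mode, pair,
                                     use_markers=use_markers)
        for t in grid:
            fp_counts[t][b] = _detected_at(scores_b, t, cfg, mode).sum()

    estimates = []
    for t in grid:
        mean_fp = float(fp_counts[t].mean())
        det = n_detected[t]
        if det == 0:
            estimates.append(
                FdrEstimate(threshold=t, mean_fp=mean_fp, n_detected=0,
                            fdr=0.0, fdr_raw=0.0, undefined=True)
            )
        else:
            raw = mean_fp / det
            estimates.append(
                FdrEstimate(threshold=t, mean_fp=mean_fp, n_detected=det,
                            fdr=min(raw, 1.0), fdr_raw=raw)
            )
    return estimates


def fdr_to_frame(estimates: Sequence[FdrEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.threshold, e.mean_fp, e.n_detected, e.fdr, e.fdr_raw, e.undefined)
            for e in estimates
        ],
        columns=["threshold", "mean_fp", "n_detected", "fdr", "fdr_raw", "undefined"],
    )
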